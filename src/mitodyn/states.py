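"""State representation for the integrated mitochondrial bioenergetics model.

The model is a 73-state differential-algebraic system:

* 65 ordinary differential states
    - 25 matrix states: 20 metabolite amounts (nmol/mg protein) plus the 5
      total cation contents (H+, K+, Na+, Mg2+, Ca2+; nmol/mg),
    - 20 intermembrane-space (IMS) states: 15 metabolite amounts plus the 5
      cation contents (nmol/mg),
    - 19 extra-mitochondrial buffer states: 15 metabolite concentrations (M)
      plus 4 total cation concentrations (buffer pH is clamped, so buffer H+
      is not a dynamic state),
    - the inner-membrane potential dpsi (mV, psi_in - psi_out, negative when
      energized);
* 5 conservation-derived species: matrix ATP, GTP, NADH, ubiquinol and
  reduced cytochrome c, each computed as pool total minus the free partner;
* 3 algebraic states: matrix water volume V_mtx (uL/mg), IMS water volume
  V_ims (uL/mg), and matrix chloride content Cl_mtx (nmol/mg, the
  electroneutrality closure).

Matrix and IMS species are integrated as amounts because both water volumes
are dynamic; concentrations are amount / volume.  Buffer species are
concentrations, and buffer-side derivatives scale with the mitochondrial
load (mg protein per mL buffer).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MATRIX_METABOLITES", "MATRIX_CATIONS", "IMS_METABOLITES", "IMS_CATIONS",
    "BUFFER_METABOLITES", "BUFFER_CATIONS", "ODE_STATE_NAMES",
    "DERIVED_NAMES", "ALGEBRAIC_NAMES", "ALL_STATE_NAMES", "STATE_UNITS",
    "N_ODE", "N_STATES", "IX", "ConservedPools", "CompartmentConvention",
    "StateVector", "pack_state", "unpack_state", "apply_conservation",
    "ConservationError", "StateNamingError",
]

# ---------------------------------------------------------------------------
# canonical state ordering (stable across the whole library)
# ---------------------------------------------------------------------------

MATRIX_METABOLITES = (
    "PYR_x", "CoASH_x", "AcCoA_x", "CIT_x", "ISOC_x", "aKG_x", "SCoA_x",
    "SUC_x", "FUM_x", "MAL_x", "OAA_x", "GLU_x", "ASP_x", "NAD_x",
    "GDP_x", "ADP_x", "AMP_x", "Pi_x", "UQ_x", "cox_i",
)
MATRIX_CATIONS = ("H_x", "K_x", "Na_x", "Mg_x", "Ca_x")

IMS_METABOLITES = (
    "PYR_i", "CIT_i", "ISOC_i", "aKG_i", "SUC_i", "FUM_i", "MAL_i",
    "GLU_i", "ASP_i", "Pi_i", "ATP_i", "ADP_i", "AMP_i", "GLC_i", "G6P_i",
)
IMS_CATIONS = ("H_i", "K_i", "Na_i", "Mg_i", "Ca_i")

BUFFER_METABOLITES = (
    "PYR_e", "CIT_e", "ISOC_e", "aKG_e", "SUC_e", "FUM_e", "MAL_e",
    "GLU_e", "ASP_e", "Pi_e", "ATP_e", "ADP_e", "AMP_e", "GLC_e", "G6P_e",
)
BUFFER_CATIONS = ("K_e", "Na_e", "Mg_e", "Ca_e")

ODE_STATE_NAMES = (
    MATRIX_METABOLITES + MATRIX_CATIONS
    + IMS_METABOLITES + IMS_CATIONS
    + BUFFER_METABOLITES + BUFFER_CATIONS
    + ("dpsi",)
)

DERIVED_NAMES = ("ATP_x", "GTP_x", "NADH_x", "UQH2_x", "cred_i")
ALGEBRAIC_NAMES = ("V_mtx", "V_ims", "Cl_x")
ALL_STATE_NAMES = ODE_STATE_NAMES + DERIVED_NAMES + ALGEBRAIC_NAMES

N_ODE = len(ODE_STATE_NAMES)          # 65
N_STATES = len(ALL_STATE_NAMES)       # 73
assert N_ODE == 65 and N_STATES == 73

#: name -> position in the ODE vector
IX = {name: i for i, name in enumerate(ODE_STATE_NAMES)}

_MTX_AMOUNTS = MATRIX_METABOLITES + MATRIX_CATIONS
_IMS_AMOUNTS = IMS_METABOLITES + IMS_CATIONS

STATE_UNITS = {}
for _n in _MTX_AMOUNTS + _IMS_AMOUNTS:
    STATE_UNITS[_n] = "nmol/mg"
for _n in BUFFER_METABOLITES + BUFFER_CATIONS:
    STATE_UNITS[_n] = "M"
STATE_UNITS["dpsi"] = "mV"
for _n in DERIVED_NAMES:
    STATE_UNITS[_n] = "nmol/mg"
STATE_UNITS["V_mtx"] = "uL/mg"
STATE_UNITS["V_ims"] = "uL/mg"
STATE_UNITS["Cl_x"] = "nmol/mg"

#: conserved pool -> (derived species, free partner(s) subtracted from the pool)
POOL_PARTNERS = {
    "NADtot": ("NADH_x", ("NAD_x",)),
    "Qtot": ("UQH2_x", ("UQ_x",)),
    "ctot": ("cred_i", ("cox_i",)),
    "ANtot_x": ("ATP_x", ("ADP_x", "AMP_x")),
    "GNtot_x": ("GTP_x", ("GDP_x",)),
}


class StateNamingError(KeyError):
    """Raised when packing/unpacking meets missing or unknown state names."""


class ConservationError(ValueError):
    """Raised when a free partner exceeds its conserved pool total."""


@dataclass(frozen=True)
class ConservedPools:
    """The five conserved moieties, in nmol per mg protein.

    Each pool is constant along any trajectory: the reduced/phosphorylated
    partner is always computed algebraically as pool total minus the free
    member(s), never integrated.
    """

    NADtot: float = 2.97     # matrix NAD + NADH
    Qtot: float = 1.35       # ubiquinone + ubiquinol
    ctot: float = 0.27       # cytochrome c (oxidized + reduced)
    ANtot_x: float = 10.0    # matrix ATP + ADP + AMP
    GNtot_x: float = 5.0     # matrix GTP + GDP

    def as_dict(self) -> dict:
        return {
            "NADtot": self.NADtot, "Qtot": self.Qtot, "ctot": self.ctot,
            "ANtot_x": self.ANtot_x, "GNtot_x": self.GNtot_x,
        }


@dataclass(frozen=True)
class CompartmentConvention:
    """Amount <-> concentration bookkeeping for the three compartments.

    Parameters
    ----------
    load : mitochondrial protein load, mg per mL of buffer.
    buffer_volume_ml : chamber volume in mL (only sets absolute totals).
    total_water : total mitochondrial water, uL per mg protein; the matrix
        and IMS water volumes always sum to this value.
    """

    load: float = 1.0
    buffer_volume_ml: float = 1.0
    total_water: float = 2.6

    def amount_to_conc(self, amount_nmol_mg: float, volume_ul_mg: float) -> float:
        """nmol/mg with uL/mg water -> molar concentration."""
        return amount_nmol_mg / volume_ul_mg * 1e-3

    def conc_to_amount(self, conc_M: float, volume_ul_mg: float) -> float:
        return conc_M * volume_ul_mg * 1e3

    def specific_to_buffer_rate(self, flux_nmol_min_mg: float) -> float:
        """nmol/min/mg leaving the buffer -> d[conc]/dt in M/min."""
        return flux_nmol_min_mg * self.load * 1e-6


@dataclass
class StateVector:
    """The 65 ODE states plus the conserved pools needed to resolve all 73."""

    y: np.ndarray
    pools: ConservedPools = field(default_factory=ConservedPools)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape != (N_ODE,):
            raise ValueError(f"expected {N_ODE} ODE states, got {self.y.shape}")

    def __getitem__(self, name: str) -> float:
        try:
            return float(self.y[IX[name]])
        except KeyError:
            raise StateNamingError(name) from None

    def copy(self) -> "StateVector":
        return StateVector(self.y.copy(), self.pools)

    def derived(self) -> dict:
        """The five conservation-derived species (nmol/mg)."""
        out = {}
        pools = self.pools.as_dict()
        for pool_name, (derived_name, partners) in POOL_PARTNERS.items():
            total = pools[pool_name]
            free = sum(self[p] for p in partners)
            value = total - free
            if value < -1e-9 * max(total, 1.0):
                raise ConservationError(
                    f"pool {pool_name}: partners {partners} sum to {free:.6g} "
                    f"which exceeds the pool total {total:.6g}")
            out[derived_name] = value
        return out


def pack_state(values: dict, pools: ConservedPools | None = None) -> StateVector:
    """Build a StateVector from a complete {name: value} mapping.

    All 65 ODE names must be present and finite.  The 5 derived names may be
    supplied; if so the conserved pools are inferred from them (pool = derived
    + partners), otherwise ``pools`` (or defaults) is used.  Algebraic names
    (V_mtx, V_ims, Cl_x) are accepted and ignored: they are recomputed from
    the ODE states by the model right-hand side.
    """
    unknown = [k for k in values if k not in ALL_STATE_NAMES]
    missing = [k for k in ODE_STATE_NAMES if k not in values]
    if unknown or missing:
        raise StateNamingError(
            f"unknown state names: {sorted(unknown)}; "
            f"missing state names: {sorted(missing)}")
    y = np.array([float(values[k]) for k in ODE_STATE_NAMES])
    if not np.all(np.isfinite(y)):
        bad = [ODE_STATE_NAMES[i] for i in np.where(~np.isfinite(y))[0]]
        raise StateNamingError(f"non-finite values for: {bad}")

    if all(d in values for d in DERIVED_NAMES):
        pool_kwargs = {}
        for pool_name, (derived_name, partners) in POOL_PARTNERS.items():
            pool_kwargs[pool_name] = float(values[derived_name]) + sum(
                float(values[p]) for p in partners)
        pools = ConservedPools(**pool_kwargs)
    elif pools is None:
        pools = ConservedPools()
    return StateVector(y, pools)


def unpack_state(state: StateVector, algebraic: dict | None = None) -> dict:
    """Return the full named 73-state mapping (inverse of :func:`pack_state`).

    ``algebraic`` optionally supplies {V_mtx, V_ims, Cl_x} (as computed by the
    model RHS); if omitted they are reported as nan placeholders.
    """
    out = {name: float(state.y[i]) for i, name in enumerate(ODE_STATE_NAMES)}
    out.update(state.derived())
    alg = algebraic or {}
    for name in ALGEBRAIC_NAMES:
        out[name] = float(alg.get(name, np.nan))
    return out


def apply_conservation(state: StateVector, pools: ConservedPools) -> dict:
    """Resolve the five derived species against ``pools``.

    Raises :class:`ConservationError` (naming the pool) if any free partner
    exceeds its pool total; values are never clipped.
    """
    return replace(state, pools=pools).derived()


def pmf_mv(dpsi_mv: float, pH_x: float, pH_e: float, T_celsius: float) -> float:
    """Proton motive force in mV: dpsi + 2.303 RT/F * dpH (paper's operator).

    The pH term is expressed in mV with the sign convention under which an
    alkaline matrix contributes negatively, so an energized mitochondrion has
    a large negative pmf (e.g. dpsi = -180 mV, dpH = 0 gives pmf = -180 mV).
    """
    z = 2.303 * 8.314462618 * (273.15 + T_celsius) / 96485.33212 * 1000.0
    return dpsi_mv - z * (pH_x - pH_e)
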