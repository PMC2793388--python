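"""Ion speciation, temperature correction and equilibrium constants.

Free cation concentrations ([K+], [Na+], [Mg2+], [Ca2+]) are obtained from
total concentrations by solving the coupled mass-balance system built from
per-ligand binding polynomials

    P_L = 1 + [H]/K_H1 + [H]^2/(K_H1 K_H2)
            + [K]/K_K + [Na]/K_Na + [Mg]/K_Mg + [Ca]/K_Ca,

where each K is a dissociation constant (M).  The bound amount of cation X
on ligand L is  L_tot * ([X]/K_X) / P_L.  The solver is a damped fixed point
on the free concentrations with a bisection fallback, robust for the stiff
EGTA/EDTA chelation present in the experimental buffers.

Temperature corrections use either a standard Q10 of 2.25 or, for reactions
with a compiled activation energy, the Arrhenius law restricted to the
linear 4-37 C range.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "R_GAS", "FARADAY", "DissociationTable", "load_dissociation_table",
    "SpeciationResult", "speciate", "total_for_free_ca",
    "TemperatureModel", "temperature_factor", "equilibrium_constant",
    "SpeciationConvergenceError", "ThermodynamicsMissingError",
]

R_GAS = 8.314462618        # J/mol/K
FARADAY = 96485.33212      # C/mol

CATIONS = ("K", "Na", "Mg", "Ca")
_KD_COLUMNS = ("KH1", "KH2", "KK", "KNa", "KMg", "KCa")


class SpeciationConvergenceError(RuntimeError):
    pass


class ThermodynamicsMissingError(KeyError):
    pass


# ---------------------------------------------------------------------------
# dissociation table
# ---------------------------------------------------------------------------

@dataclass
class DissociationTable:
    """Dissociation constants, one row per ligand.

    ``kd[ligand]`` maps to a 6-vector (KH1, KH2, KK, KNa, KMg, KCa) in M;
    ``inf`` encodes "does not bind".
    """

    kd: dict = field(default_factory=dict)

    def __contains__(self, ligand):
        return ligand in self.kd

    def matrix_for(self, ligands) -> np.ndarray:
        """(n_ligands, 6) Kd array in the order given, for the fast solver."""
        rows = []
        for lig in ligands:
            if lig not in self.kd:
                raise ThermodynamicsMissingError(
                    f"no dissociation constants for ligand {lig!r}")
            rows.append(self.kd[lig])
        return np.array(rows, dtype=float)

    def binding_polynomial(self, ligand, H, K=0.0, Na=0.0, Mg=0.0, Ca=0.0):
        kh1, kh2, kk, kna, kmg, kca = self.kd[ligand]
        p = 1.0 + H / kh1 + H * H / (kh1 * kh2)
        p += K / kk + Na / kna + Mg / kmg + Ca / kca
        return p


def load_dissociation_table(path=None) -> DissociationTable:
    """Load the shipped dissociation-constant table (or a user override)."""
    if path is None:
        src = resources.files("mitodyn.data").joinpath(
            "dissociation_constants.tsv")
        text = src.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    kd = {}
    header = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if header is None:
            header = parts
            if tuple(header[1:]) != _KD_COLUMNS:
                raise ValueError(f"unexpected columns {header[1:]}")
            continue
        lig, *vals = parts
        row = [math.inf if v == "inf" else float(v) for v in vals]
        if any(v <= 0 for v in row):
            raise ValueError(f"non-positive dissociation constant for {lig}")
        kd[lig] = np.array(row)
    return DissociationTable(kd)


_DEFAULT_TABLE = None


def default_dissociation_table() -> DissociationTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_dissociation_table()
    return _DEFAULT_TABLE


# ---------------------------------------------------------------------------
# speciation solver
# ---------------------------------------------------------------------------

@dataclass
class SpeciationResult:
    free: dict                 # free cation concentrations, M (incl. "H")
    bound: dict                # bound[(ligand, cation)] -> M bound
    ligand_free: dict          # fully unchelated, unprotonated ligand, M
    poly: dict                 # binding polynomial per ligand
    residual: float
    iterations: int


def _inv_kd(kdm: np.ndarray) -> np.ndarray:
    out = np.zeros_like(kdm[:, 2:6])
    finite = np.isfinite(kdm[:, 2:6])
    out[finite] = 1.0 / kdm[:, 2:6][finite]
    return out


def _solve_free(lig_tot: np.ndarray, kdm: np.ndarray, cat_tot: np.ndarray,
                H: float, tol: float = 1e-12, max_iter: int = 500,
                x0: np.ndarray | None = None,
                inv_kd: np.ndarray | None = None):
    """Damped fixed point for free (K, Na, Mg, Ca) given totals.

    Returns (free (4,), P (n_lig,), iterations).  Falls back to per-cation
    bisection if the fixed point stalls.
    """
    hterm = H / kdm[:, 0] + H * H / (kdm[:, 0] * kdm[:, 1])
    if inv_kd is None:
        inv_kd = _inv_kd(kdm)

    free = cat_tot.copy() if x0 is None else np.minimum(x0, cat_tot)
    free = np.where(cat_tot > 0, np.maximum(free, 1e-30), 0.0)
    P = None
    for it in range(1, max_iter + 1):
        P = 1.0 + hterm + (inv_kd * free).sum(axis=1)
        # load factor: sum_L L_tot / (P_L * K_XL)
        load = (lig_tot[:, None] * inv_kd / P[:, None]).sum(axis=0)
        new = cat_tot / (1.0 + load)
        if np.all(np.abs(new - free) <= tol * np.maximum(new, 1e-300)):
            return new, 1.0 + hterm + (inv_kd * new).sum(axis=1), it
        # damping stabilizes the stiff EGTA/EDTA case
        free = np.where(cat_tot > 0, np.sqrt(free * np.maximum(new, 1e-300)),
                        0.0)
    # bisection fallback, one cation at a time (Gauss-Seidel sweeps)
    for _ in range(50):
        for j in range(4):
            if cat_tot[j] <= 0:
                free[j] = 0.0
                continue
            lo, hi = 0.0, cat_tot[j]
            for _ in range(80):
                mid = 0.5 * (lo + hi)
                free[j] = mid
                P = 1.0 + hterm + (inv_kd * free).sum(axis=1)
                bound = (lig_tot * inv_kd[:, j] / P).sum() * mid
                if mid + bound > cat_tot[j]:
                    hi = mid
                else:
                    lo = mid
            free[j] = 0.5 * (lo + hi)
    P = 1.0 + hterm + (inv_kd * free).sum(axis=1)
    load = (lig_tot[:, None] * inv_kd / P[:, None]).sum(axis=0)
    resid = np.max(np.abs(free * (1.0 + load) - cat_tot)
                   / np.maximum(cat_tot, 1e-300))
    if resid > 1e-6:
        raise SpeciationConvergenceError(
            f"speciation failed to converge, residual {resid:.3g}")
    return free, P, max_iter


def speciate(ligand_totals: dict, cation_totals: dict, pH: float,
             table: DissociationTable | None = None,
             fixed_free: dict | None = None,
             tol: float = 1e-12) -> SpeciationResult:
    """Solve the speciation system.

    Parameters
    ----------
    ligand_totals : {ligand: total M}.
    cation_totals : {cation: total M} for any of K, Na, Mg, Ca.  Cations
        absent are taken as zero.
    pH : fixes the free proton concentration.
    fixed_free : optionally clamp a cation's *free* concentration (e.g.
        ``{"Ca": 550e-9}``); its total is then implied, not conserved.
    """
    if not (0.0 < pH < 14.0):
        raise ValueError(f"pH {pH} outside (0, 14)")
    for name, v in {**ligand_totals, **cation_totals}.items():
        if v < 0:
            raise ValueError(f"negative total for {name}: {v}")
    table = table or default_dissociation_table()
    fixed_free = fixed_free or {}
    ligands = [lig for lig, tot in ligand_totals.items() if tot > 0]
    lig_tot = np.array([ligand_totals[lig] for lig in ligands])
    kdm = (table.matrix_for(ligands) if ligands
           else np.zeros((0, 6)))
    H = 10.0 ** (-pH)

    cat_tot = np.array([float(cation_totals.get(c, 0.0)) for c in CATIONS])
    clamp = np.array([c in fixed_free for c in CATIONS])
    # clamped cations: run the solver with their free value imposed by
    # giving them an effectively infinite reservoir, then back out totals
    free = np.where(clamp,
                    [float(fixed_free.get(c, 0.0)) for c in CATIONS],
                    cat_tot)
    if ligands:
        if clamp.any():
            free_solved, P, its = _solve_free_clamped(
                lig_tot, kdm, cat_tot, clamp, free, H, tol)
        else:
            free_solved, P, its = _solve_free(lig_tot, kdm, cat_tot, H, tol)
    else:
        free_solved, P, its = free.copy(), np.zeros(0), 0

    inv_kd = np.zeros((len(ligands), 4))
    if ligands:
        finite = np.isfinite(kdm[:, 2:6])
        inv_kd[finite] = 1.0 / kdm[:, 2:6][finite]

    bound = {}
    total_out = dict(zip(CATIONS, cat_tot))
    for i, lig in enumerate(ligands):
        for j, c in enumerate(CATIONS):
            bound[(lig, c)] = float(lig_tot[i] * free_solved[j]
                                    * inv_kd[i, j] / P[i])
    for j, c in enumerate(CATIONS):
        if clamp[j]:
            total_out[c] = free_solved[j] + sum(
                bound[(lig, c)] for lig in ligands)

    lig_free = {lig: float(lig_tot[i] / P[i]) for i, lig in enumerate(ligands)}
    for lig, tot in ligand_totals.items():
        if tot == 0:
            lig_free[lig] = 0.0
    resid = 0.0
    for j, c in enumerate(CATIONS):
        if clamp[j] or total_out[c] == 0:
            continue
        back = free_solved[j] + sum(bound[(lig, c)] for lig in ligands)
        resid = max(resid, abs(back - total_out[c]) / total_out[c])
    freed = dict(zip(CATIONS, map(float, free_solved)))
    freed["H"] = H
    return SpeciationResult(free=freed, bound=bound, ligand_free=lig_free,
                            poly={lig: float(P[i]) for i, lig in
                                  enumerate(ligands)},
                            residual=float(resid), iterations=its)


def _solve_free_clamped(lig_tot, kdm, cat_tot, clamp, free_init, H, tol):
    """Fixed point with some cations' free values held constant."""
    hterm = H / kdm[:, 0] + H * H / (kdm[:, 0] * kdm[:, 1])
    inv_kd = np.zeros_like(kdm[:, 2:6])
    finite = np.isfinite(kdm[:, 2:6])
    inv_kd[finite] = 1.0 / kdm[:, 2:6][finite]
    free = free_init.astype(float).copy()
    free[~clamp] = np.maximum(cat_tot[~clamp], 1e-30)
    free[(~clamp) & (cat_tot <= 0)] = 0.0
    for it in range(1, 500 + 1):
        P = 1.0 + hterm + (inv_kd * free).sum(axis=1)
        load = (lig_tot[:, None] * inv_kd / P[:, None]).sum(axis=0)
        new = np.where(clamp, free, cat_tot / (1.0 + load))
        new[(~clamp) & (cat_tot <= 0)] = 0.0
        if np.all(np.abs(new - free)
                  <= tol * np.maximum(np.abs(new), 1e-300)):
            return new, 1.0 + hterm + (inv_kd * new).sum(axis=1), it
        mixed = np.sqrt(np.maximum(free, 1e-300)
                        * np.maximum(new, 1e-300))
        free = np.where(clamp, new, np.where(cat_tot > 0, mixed, 0.0))
    raise SpeciationConvergenceError("clamped speciation did not converge")


def total_for_free_ca(target_free_ca: float, ligand_totals: dict,
                      cation_totals: dict, pH: float,
                      table: DissociationTable | None = None) -> float:
    """Total CaCl2 needed so the buffer's free [Ca2+] equals the target.

    This is the "clamp free calcium" mode: chelator-containing buffers are
    prepared against a stated free level, so the total is the derived
    quantity.
    """
    res = speciate(ligand_totals, cation_totals, pH, table=table,
                   fixed_free={"Ca": target_free_ca})
    lig = [l for l, t in ligand_totals.items() if t > 0]
    return target_free_ca + sum(res.bound[(l, "Ca")] for l in lig)


# ---------------------------------------------------------------------------
# temperature model
# ---------------------------------------------------------------------------

def _load_ea_table():
    src = resources.files("mitodyn.data").joinpath("activation_energies.tsv")
    ea = {}
    header_seen = False
    for line in src.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if not header_seen:
            header_seen = True
            continue
        rxn, val = line.split("\t")
        ea[rxn] = float(val)
    return ea


@dataclass(frozen=True)
class TemperatureModel:
    """Q10 / Arrhenius rate correction relative to the reference temperature.

    Reactions listed in the activation-energy table use the Arrhenius form
    exp((Ea/R) (1/Tref - 1/T)); all others use Q10^((T - Tref)/10) with the
    standard Q10 of 2.25.
    """

    T_ref: float = 25.0          # degrees C (Table 2 reference)
    q10: float = 2.25
    ea: dict = field(default_factory=_load_ea_table)

    def factor(self, reaction_id: str, T: float) -> float:
        if not (4.0 <= T <= 37.0):
            warnings.warn(
                f"temperature {T} C outside the linear Arrhenius range "
                "4-37 C; extrapolating", stacklevel=2)
        if reaction_id in self.ea:
            tref_k = self.T_ref + 273.15
            t_k = T + 273.15
            return math.exp(self.ea[reaction_id] / R_GAS
                            * (1.0 / tref_k - 1.0 / t_k))
        return self.q10 ** ((T - self.T_ref) / 10.0)


def temperature_factor(reaction_id: str, T: float,
                       model: TemperatureModel | None = None) -> float:
    return (model or TemperatureModel()).factor(reaction_id, T)


# ---------------------------------------------------------------------------
# apparent equilibrium constants
# ---------------------------------------------------------------------------

#: apparent equilibrium constants of the scalar (non-transport) reactions at
#: pH 7, 25 C, with water/CO2 at unit activity, plus the number of protons
#: released per forward turnover under the model's nominal charge
#: convention.  Keq for the proton-pumping reactions (CI, CIII, CIV, F1FO)
#: and the transporters is membrane-potential dependent and is evaluated
#: inside the rate laws instead.
KEQ_REF = {
    # reaction: (Keq at pH 7, protons released nu_H, ligand stoichiometry)
    "PDH": (7.2e5, 0, {}),
    "CS": (2.3e5, 1, {"CIT": 1}),
    "ACH": (0.067, 0, {"CIT": -1, "ISOC": 1}),
    "IDH": (1.0e2, 0, {"ISOC": -1, "aKG": 1}),
    "aKGDH": (7.0e5, 0, {"aKG": -1}),
    "SCoAS": (3.7, 0, {"GDP": -1, "Pi": -1, "SUC": 1, "GTP": 1}),
    "SDH": (3.0, 0, {"SUC": -1, "FUM": 1}),
    "FH": (4.4, 0, {"FUM": -1, "MAL": 1}),
    "MDH": (2.8e-5, 1, {"MAL": -1}),
    "NDK": (1.0, 0, {"GTP": -1, "ADP": -1, "GDP": 1, "ATP": 1}),
    "GOT": (0.15, 0, {"aKG": -1}),
    "AK": (1.0, 0, {"ADP": -2, "ATP": 1, "AMP": 1}),
    "HK": (8.8e2, 1, {"ATP": -1, "ADP": 1}),
}


def equilibrium_constant(reaction_id: str, T: float = 25.0, pH: float = 7.0,
                         free_mg: float = 1e-3, free_k: float = 0.13,
                         table: DissociationTable | None = None) -> float:
    """Apparent Keq of a scalar reaction at the given pH and free cations.

    The pH correction follows the proton stoichiometry (a reaction releasing
    nu_H protons has Keq_app = Keq_ref * (1e-7/[H+])^nu_H); Mg2+/K+
    corrections re-weight each speciating reactant by the ratio of its
    binding polynomial to the reference-condition value.
    """
    if reaction_id not in KEQ_REF:
        raise ThermodynamicsMissingError(
            f"no equilibrium data for reaction {reaction_id!r}")
    keq_ref, nu_h, ligs = KEQ_REF[reaction_id]
    table = table or default_dissociation_table()
    H = 10.0 ** (-pH)
    k = keq_ref * (1e-7 / H) ** nu_h
    for lig, stoich in ligs.items():
        if stoich == 0 or lig not in table:
            continue
        p_now = table.binding_polynomial(lig, H, K=free_k, Mg=free_mg)
        p_ref = table.binding_polynomial(lig, 1e-7, K=0.13, Mg=1e-3)
        # a product that binds more strongly under current conditions has a
        # larger polynomial -> larger apparent Keq
        k *= (p_now / p_ref) ** stoich
    return k
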