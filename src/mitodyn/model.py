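"""Right-hand-side assembly and stiff integration of the 73-state DAE.

The DAE is reduced to an ODE with embedded algebra: the five conservation
relations, both water volumes and the matrix chloride content are evaluated
inside the right-hand side (index-1 elimination), so a standard stiff ODE
solver integrates the 65 differential states.

Bookkeeping conventions
-----------------------
* Matrix and IMS species are amounts (nmol/mg); buffer species are molar.
* The membrane potential obeys  c_mem * d(dpsi)/dt = sum of signed charge
  fluxes (positive charge entering the matrix depolarizes, i.e. makes dpsi
  less negative).
* Matrix/IMS pH follow a linear buffering-capacity mapping from titratable
  proton content: pH = pH_anchor - (content/volume - c_anchor)/beta_H.
* The matrix water volume solves the osmotic balance (matrix osmolality =
  buffer osmolality); the IMS volume is the fixed total water minus the
  matrix volume; matrix Cl- is the electroneutrality closure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .states import (IX, N_ODE, ODE_STATE_NAMES, MATRIX_METABOLITES,
                     IMS_METABOLITES, BUFFER_METABOLITES, ConservedPools,
                     StateVector)
from .thermo import default_dissociation_table, _solve_free
from .rates import RateContext, all_fluxes, FLUX_NAMES
from .params import ParameterSet, load_parameters

__all__ = ["SolverSettings", "SimContext", "Model", "Trajectory",
           "CHARGE_COEFF", "STOICH", "NOMINAL_CHARGE", "IntegrationError"]


class IntegrationError(RuntimeError):
    def __init__(self, msg, t_last=None, y_last=None):
        super().__init__(msg)
        self.t_last = t_last
        self.y_last = y_last


# ---------------------------------------------------------------------------
# stoichiometry
# ---------------------------------------------------------------------------

#: nominal ionic charge (magnitude of the anionic charge) per species at
#: physiological pH; used for the proton ledger and the Cl- closure.
NOMINAL_CHARGE = {
    "PYR": -1, "CoASH": -4, "AcCoA": -4, "CIT": -3, "ISOC": -3, "aKG": -2,
    "SCoA": -5, "SUC": -2, "FUM": -2, "MAL": -2, "OAA": -2, "GLU": -1,
    "ASP": -1, "NAD": -1, "NADH": -2, "GDP": -3, "GTP": -4, "ADP": -3,
    "ATP": -4, "AMP": -2, "Pi": -2, "UQ": 0, "UQH2": 0, "GLC": 0, "G6P": -2,
}

#: per-reaction state increments (nmol/mg per unit flux).  Matrix scalar
#: protons (from the nominal-charge ledger) and the explicit pump/transport
#: proton movements are listed under H_x / H_i; CHARGE_COEFF lists the net
#: positive charge entering the matrix per unit flux.
STOICH = {
    "PDH": {"PYR_x": -1, "CoASH_x": -1, "NAD_x": -1, "AcCoA_x": 1},
    "CS": {"OAA_x": -1, "AcCoA_x": -1, "CoASH_x": 1, "CIT_x": 1, "H_x": 1},
    "ACH": {"CIT_x": -1, "ISOC_x": 1},
    "IDH": {"ISOC_x": -1, "NAD_x": -1, "aKG_x": 1},
    "aKGDH": {"aKG_x": -1, "CoASH_x": -1, "NAD_x": -1, "SCoA_x": 1},
    "SCoAS": {"SCoA_x": -1, "GDP_x": -1, "Pi_x": -1, "SUC_x": 1,
              "CoASH_x": 1},
    "SDH": {"SUC_x": -1, "UQ_x": -1, "FUM_x": 1},
    "FH": {"FUM_x": -1, "MAL_x": 1},
    "MDH": {"MAL_x": -1, "NAD_x": -1, "OAA_x": 1, "H_x": 1},
    "NDK": {"GDP_x": 1, "ADP_x": -1},
    "GOT": {"ASP_x": -1, "aKG_x": -1, "OAA_x": 1, "GLU_x": 1},
    "CI": {"NAD_x": 1, "UQ_x": -1, "H_x": -5, "H_i": 4},
    "CIII": {"UQ_x": 1, "cox_i": -2, "H_x": -2, "H_i": 4},
    "CIV": {"cox_i": 2, "H_x": -4, "H_i": 2},
    "F1FO": {"ADP_x": -1, "Pi_x": -1, "H_x": 8.0 / 3.0 - 1.0,
             "H_i": -8.0 / 3.0},
    "AK": {"ADP_i": -2, "ATP_i": 1, "AMP_i": 1},
    "GAE": {"GLU_x": 1, "ASP_x": -1, "GLU_i": -1, "ASP_i": 1,
            "H_x": 1, "H_i": -1},
    "OME": {"aKG_x": 1, "MAL_x": -1, "aKG_i": -1, "MAL_i": 1},
    "PYRH": {"PYR_x": 1, "PYR_i": -1, "H_x": 1, "H_i": -1},
    "GLUH": {"GLU_x": 1, "GLU_i": -1, "H_x": 1, "H_i": -1},
    "CITMAL": {"CIT_x": 1, "CIT_i": -1, "MAL_x": -1, "MAL_i": 1,
               "H_x": 1, "H_i": -1},
    "ISOCMAL": {"ISOC_x": 1, "ISOC_i": -1, "MAL_x": -1, "MAL_i": 1,
                "H_x": 1, "H_i": -1},
    "SUCPI": {"SUC_x": -1, "SUC_i": 1, "Pi_x": 1, "Pi_i": -1},
    "MALPI": {"MAL_x": -1, "MAL_i": 1, "Pi_x": 1, "Pi_i": -1},
    "ANT": {"ADP_x": 1, "ATP_i": 1, "ADP_i": -1},
    "PIC": {"Pi_x": 1, "Pi_i": -1, "H_x": 2, "H_i": -2},
    "mHleak": {"H_x": 1, "H_i": -1},
    "mKHE": {"K_x": -1, "K_i": 1, "H_x": 1, "H_i": -1},
    "mKATP": {"K_x": 1, "K_i": -1},
    "mKleak": {"K_x": 1, "K_i": -1},
    "CaUNI": {"Ca_x": 1, "Ca_i": -1},
    "mNCE": {"Ca_x": -1, "Ca_i": 1, "Na_x": 3, "Na_i": -3},
    "mNHE": {"Na_x": -1, "Na_i": 1, "H_x": 1, "H_i": -1},
    "HK": {},      # buffer-side reaction, handled separately
}

#: net positive charge entering the matrix per unit (forward) flux
CHARGE_COEFF = {
    "CI": -4.0, "CIII": -2.0, "CIV": -4.0, "F1FO": 8.0 / 3.0,
    "ANT": 1.0, "GAE": 1.0, "mHleak": 1.0, "mKleak": 1.0, "mKATP": 1.0,
    "CaUNI": 2.0, "mNCE": 1.0,
}

#: buffer-side reactions: species increments in "buffer amount" units (the
#: model converts with load * 1e-6 to M/min)
BUFFER_STOICH = {
    "HK": {"GLC_e": -1, "ATP_e": -1, "G6P_e": 1, "ADP_e": 1},
}

_MATRIX_LIGANDS = ("ATP", "ADP", "AMP", "GTP", "GDP", "Pi", "CIT", "ISOC",
                   "MAL", "SUC", "FUM", "aKG")
_OUTER_LIGANDS = ("ATP", "ADP", "AMP", "Pi", "CIT", "ISOC", "MAL", "SUC",
                  "FUM", "aKG", "GLU", "EGTA", "EDTA")

# matrix metabolites participating in the osmotic/charge ledgers (pool
# members are replaced by their constant pool totals)
_OSMO_SPECIES = ("PYR_x", "CoASH_x", "AcCoA_x", "CIT_x", "ISOC_x", "aKG_x",
                 "SCoA_x", "SUC_x", "FUM_x", "MAL_x", "OAA_x", "GLU_x",
                 "ASP_x", "Pi_x")


@dataclass
class SolverSettings:
    """Stiff-solver tolerances (defaults per the reference configuration)."""

    rtol: float = 1e-3
    atol_matrix: float = 1e-9
    atol_other: float = 1e-6
    max_step: float = np.inf
    ss_threshold: float = 1e-6    # steady-state detection, 1/min
    method: str = "BDF"

    def atol_vector(self) -> np.ndarray:
        atol = np.full(N_ODE, self.atol_other)
        for i, name in enumerate(ODE_STATE_NAMES):
            if name.endswith("_x") or name.endswith("_i"):
                atol[i] = self.atol_matrix * 1e3   # amounts are nmol/mg
        atol[IX["dpsi"]] = 1e-3
        return atol

    @classmethod
    def strict(cls) -> "SolverSettings":
        """The stricter tolerances used for sensitivity analysis."""
        return cls(rtol=1e-9, atol_matrix=1e-12, atol_other=1e-9)


@dataclass
class SimContext:
    """Everything besides the state needed to evaluate the RHS."""

    pset: ParameterSet
    T: float = 25.0               # C
    pH_e: float = 7.2             # clamped buffer pH
    osm_e: float = 0.290          # buffer osmolarity, Osm
    load: float = 1.0             # mg protein / mL buffer
    egta: float = 0.0             # buffer chelators, M
    edta: float = 0.0
    clamp_free_ca: float | None = None
    khe_bose: bool = False
    pools: ConservedPools = field(default_factory=ConservedPools)

    def with_additions(self, **kw) -> "SimContext":
        return replace(self, **kw)


class Model:
    """Evaluates fluxes and derivatives and integrates the system."""

    def __init__(self, ctx: SimContext):
        self.ctx = ctx
        self.p = ctx.pset
        self.table = default_dissociation_table()
        self._kd_matrix = self.table.matrix_for(_MATRIX_LIGANDS)
        self._kd_outer = self.table.matrix_for(_OUTER_LIGANDS)
        from .thermo import _inv_kd
        self._inv_kd = {"x": _inv_kd(self._kd_matrix),
                        "i": _inv_kd(self._kd_outer),
                        "e": _inv_kd(self._kd_outer)}
        from .thermo import TemperatureModel
        tm = TemperatureModel()
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            self.tf = {r: tm.factor(r, ctx.T)
                       for r in FLUX_NAMES + ("TCC", "DCC")}
        # reference-state consistency constants (set by calibrate_reference)
        self.n_imp = None
        self.x_imp = None
        self._stoich_idx = [
            (name, [(IX[st], co) for st, co in STOICH[name].items()])
            for name in FLUX_NAMES]
        self._buffer_idx = [
            (name, [(IX[st], co) for st, co in spec.items()])
            for name, spec in BUFFER_STOICH.items()]

    # -- small helpers -----------------------------------------------------

    def _ph_from_content(self, content, volume):
        p = self.p
        c = content / volume * 1e-3
        return (p["general", "pH_anchor"]
                - (c - p["general", "cH_anchor"]) / p["general", "beta_H"])

    def proton_content_for_ph(self, pH, volume):
        p = self.p
        c = (p["general", "cH_anchor"]
             + (p["general", "pH_anchor"] - pH) * p["general", "beta_H"])
        return c * volume * 1e3

    # -- algebraic states --------------------------------------------------

    def chloride(self, y) -> float:
        """Matrix Cl- content from the electroneutrality closure (nmol/mg)."""
        pools = self.ctx.pools
        cat = (y[IX["K_x"]] + y[IX["Na_x"]]
               + 2.0 * y[IX["Mg_x"]] + 2.0 * y[IX["Ca_x"]])
        anion = 0.0
        for name in _OSMO_SPECIES:
            anion += -NOMINAL_CHARGE[name[:-2]] * max(y[IX[name]], 0.0)
        # pool members: charge expressed through the free partners
        nad = y[IX["NAD_x"]]
        anion += 2.0 * pools.NADtot - nad
        adp, amp = y[IX["ADP_x"]], y[IX["AMP_x"]]
        anion += 4.0 * pools.ANtot_x - adp - 2.0 * amp
        gdp = y[IX["GDP_x"]]
        anion += 4.0 * pools.GNtot_x - gdp
        return max(cat - anion - self.x_imp, 0.0)

    def osmotic_content(self, y, cl) -> float:
        """Total osmotically active matrix content (nmol/mg)."""
        pools = self.ctx.pools
        tot = cl + self.n_imp
        for name in _OSMO_SPECIES:
            tot += max(y[IX[name]], 0.0)
        tot += pools.NADtot + pools.ANtot_x + pools.GNtot_x + pools.Qtot
        tot += (y[IX["K_x"]] + y[IX["Na_x"]] + y[IX["Mg_x"]]
                + y[IX["Ca_x"]])
        return tot

    def volumes(self, y):
        """(V_mtx, V_ims, Cl_x) from the osmotic and charge closures."""
        if self.ctx.osm_e <= 0:
            raise ValueError("buffer osmolarity must be positive")
        cl = self.chloride(y)
        content = self.osmotic_content(y, cl)
        v_mtx = content / (self.ctx.osm_e * 1e3)
        total = self.p["general", "total_water"]
        v_mtx = min(v_mtx, total - 0.05)
        v_ims = total - v_mtx
        return v_mtx, v_ims, cl

    def calibrate_reference(self, y0, cl_ref_mM=15.0):
        """Fix the impermeant osmolyte and charge constants so the reference
        state is osmotically and electrically consistent at V_mtx_ref."""
        p = self.p
        v_ref = p["general", "V_mtx_ref"]
        self.x_imp = 0.0
        cl_ref = cl_ref_mM * 1e-3 * v_ref * 1e3
        # chloride() with x_imp = 0 returns cat - anion; impermanent charge
        # is whatever closes electroneutrality at the reference Cl-
        self.n_imp = 0.0
        gap = self.chloride(y0)
        self.x_imp = gap - cl_ref
        content = self.osmotic_content(y0, cl_ref)
        target = p["general", "osm_ref"] * 1e3 * v_ref
        self.n_imp = max(target - content, 0.0)
        return self

    # -- speciation --------------------------------------------------------

    def _speciate_compartment(self, key, lig_names, kd, lig_tot, cat_tot,
                              H, clamp_ca=None):
        if clamp_ca is None:
            free, P, _ = _solve_free(lig_tot, kd, cat_tot, H, tol=1e-10,
                                     inv_kd=self._inv_kd[key])
        else:
            from .thermo import _solve_free_clamped
            clamp = np.array([False, False, False, True])
            init = cat_tot.copy()
            init[3] = clamp_ca
            free, P, _ = _solve_free_clamped(lig_tot, kd, cat_tot, clamp,
                                             init, H, tol=1e-10)
        return free, P

    # -- the right-hand side ----------------------------------------------

    def rhs(self, t, y, return_extras=False):
        ctx = self.ctx
        p = self.p
        pools = ctx.pools
        yc = np.maximum(y, 0.0)

        v_mtx, v_ims, cl = self.volumes(yc)
        pH_x = min(max(self._ph_from_content(yc[IX["H_x"]], v_mtx), 3.0),
                   11.0)
        pH_i = min(max(self._ph_from_content(yc[IX["H_i"]], v_ims), 3.0),
                   11.0)
        hx = 10.0 ** (-pH_x)
        hi = 10.0 ** (-pH_i)
        he = 10.0 ** (-ctx.pH_e)

        # concentrations
        def mtx_conc(name):
            return yc[IX[name]] / v_mtx * 1e-3

        def ims_conc(name):
            return yc[IX[name]] / v_ims * 1e-3

        # derived pool partners, clipped at zero against solver overshoot
        derived = {
            "ATP_x": max(pools.ANtot_x - yc[IX["ADP_x"]]
                         - yc[IX["AMP_x"]], 0.0),
            "GTP_x": max(pools.GNtot_x - yc[IX["GDP_x"]], 0.0),
            "NADH_x": max(pools.NADtot - yc[IX["NAD_x"]], 0.0),
            "UQH2_x": max(pools.Qtot - yc[IX["UQ_x"]], 0.0),
            "cred_i": max(pools.ctot - yc[IX["cox_i"]], 0.0),
        }
        cx = {name[:-2]: mtx_conc(name) for name in MATRIX_METABOLITES}
        cx["ATP"] = derived["ATP_x"] / v_mtx * 1e-3
        cx["GTP"] = derived["GTP_x"] / v_mtx * 1e-3
        cx["NADH"] = derived["NADH_x"] / v_mtx * 1e-3
        cx["UQH2"] = derived["UQH2_x"] / v_mtx * 1e-3
        cx["NAD"] = mtx_conc("NAD_x")
        cx["UQ"] = mtx_conc("UQ_x")
        ci = {name[:-2]: ims_conc(name) for name in IMS_METABOLITES}
        ci["cox"] = ims_conc("cox_i")
        ci["cred"] = derived["cred_i"] / v_ims * 1e-3
        ce = {name[:-2]: float(yc[IX[name]]) for name in BUFFER_METABOLITES}

        # matrix speciation
        lig_x = np.array([cx[l] for l in _MATRIX_LIGANDS])
        cat_x = np.array([mtx_conc("K_x"), mtx_conc("Na_x"),
                          mtx_conc("Mg_x"), mtx_conc("Ca_x")])
        free_x, P_x = self._speciate_compartment(
            "x", _MATRIX_LIGANDS, self._kd_matrix, lig_x, cat_x, hx)
        fx = {"H": hx, "K": free_x[0], "Na": free_x[1], "Mg": free_x[2],
              "Ca": free_x[3]}
        poly_x = dict(zip(_MATRIX_LIGANDS, P_x))
        ligfree_x = {l: cx[l] / poly_x[l] for l in ("ATP", "ADP")}

        # IMS speciation (chelators permeate the outer membrane freely)
        lig_i = np.array([ci.get(l, 0.0) for l in _OUTER_LIGANDS])
        lig_i[_OUTER_LIGANDS.index("EGTA")] = ctx.egta
        lig_i[_OUTER_LIGANDS.index("EDTA")] = ctx.edta
        cat_i = np.array([ims_conc("K_i"), ims_conc("Na_i"),
                          ims_conc("Mg_i"), ims_conc("Ca_i")])
        free_i, P_i = self._speciate_compartment(
            "i", _OUTER_LIGANDS, self._kd_outer, lig_i, cat_i, hi,
            clamp_ca=ctx.clamp_free_ca)
        fi = {"H": hi, "K": free_i[0], "Na": free_i[1], "Mg": free_i[2],
              "Ca": free_i[3]}
        iatp = _OUTER_LIGANDS.index("ATP")
        iadp = _OUTER_LIGANDS.index("ADP")
        ligfree_i = {"ATP": ci["ATP"] / P_i[iatp] if ci["ATP"] > 0 else 0.0,
                     "ADP": ci["ADP"] / P_i[iadp] if ci["ADP"] > 0 else 0.0}
        # MgATP / MgADP sensed by the mKATP channel (IMS side)
        kd_mg_atp = self._kd_outer[iatp, 4]
        kd_mg_adp = self._kd_outer[iadp, 4]
        ci["MgATP"] = ci["ATP"] * (fi["Mg"] / kd_mg_atp) / P_i[iatp]
        ci["MgADP"] = ci["ADP"] * (fi["Mg"] / kd_mg_adp) / P_i[iadp]

        # buffer speciation
        lig_e = np.array([ce.get(l, 0.0) for l in _OUTER_LIGANDS])
        lig_e[_OUTER_LIGANDS.index("EGTA")] = ctx.egta
        lig_e[_OUTER_LIGANDS.index("EDTA")] = ctx.edta
        cat_e = np.array([yc[IX["K_e"]], yc[IX["Na_e"]], yc[IX["Mg_e"]],
                          yc[IX["Ca_e"]]])
        free_e, P_e = self._speciate_compartment(
            "e", _OUTER_LIGANDS, self._kd_outer, lig_e, cat_e, he,
            clamp_ca=ctx.clamp_free_ca)
        fe = {"H": he, "K": free_e[0], "Na": free_e[1], "Mg": free_e[2],
              "Ca": free_e[3]}

        rctx = RateContext(cx=cx, ci=ci, ce=ce, fx=fx, fi=fi, fe=fe,
                           ligfree_x=ligfree_x, ligfree_i=ligfree_i,
                           poly_x=poly_x, dpsi=float(y[IX["dpsi"]]),
                           V_mtx=v_mtx, T=ctx.T, tf=self.tf, p=p,
                           khe_bose=ctx.khe_bose)
        J = all_fluxes(rctx)

        dy = np.zeros(N_ODE)
        for name, pairs in self._stoich_idx:
            j = J[name]
            if j == 0.0:
                continue
            for idx, co in pairs:
                dy[idx] += co * j

        # membrane potential from the charge ledger
        q = 0.0
        for name, co in CHARGE_COEFF.items():
            q += co * J[name]
        dy[IX["dpsi"]] = q / p["general", "c_mem"]

        # outer-membrane permeation (IMS <-> buffer)
        kom = p["general", "k_OM"]
        scale = ctx.load * 1e-6
        for name in IMS_METABOLITES:
            base = name[:-2]
            j_om = kom * (ce[base] - ci[base]) * 1e3
            dy[IX[name]] += j_om
            dy[IX[base + "_e"]] -= j_om * scale
        for cat, jdx in (("K", 0), ("Na", 1), ("Mg", 2), ("Ca", 3)):
            ce_tot = float(cat_e[jdx])
            ci_tot = float(cat_i[jdx])
            j_om = kom * (ce_tot - ci_tot) * 1e3
            dy[IX[f"{cat}_i"]] += j_om
            dy[IX[f"{cat}_e"]] -= j_om * scale
        # proton relaxation of the IMS toward the clamped buffer pH: an IMS
        # more acidic than the buffer (pH_i < pH_e) loses proton content
        j_h = kom * p["general", "beta_H"] * 1e3 * (pH_i - ctx.pH_e)
        dy[IX["H_i"]] += j_h

        # buffer-side reactions
        for name, pairs in self._buffer_idx:
            j = J[name] * scale
            for idx, co in pairs:
                dy[idx] += co * j

        if ctx.clamp_free_ca is not None:
            dy[IX["Ca_e"]] = 0.0
            dy[IX["Ca_i"]] = 0.0

        if return_extras:
            extras = {
                "V_mtx": v_mtx, "V_ims": v_ims, "Cl_x": cl,
                "pH_x": pH_x, "pH_i": pH_i, "fluxes": J,
                "free_x": fx, "free_i": fi, "free_e": fe,
                "charge_flux": q,
                "MVO2": J["CIV"],
                "NADH_frac": derived["NADH_x"] / pools.NADtot,
                "cred_frac": derived["cred_i"] / pools.ctot,
            }
            return dy, extras
        return dy

    # -- integration -------------------------------------------------------

    def integrate(self, y0, t_span, settings: SolverSettings | None = None,
                  n_save=200) -> "Trajectory":
        settings = settings or SolverSettings()
        if not t_span[1] > t_span[0]:
            raise ValueError("t_span must be increasing")
        t_eval = np.linspace(t_span[0], t_span[1], n_save)
        methods = [settings.method] + [m for m in ("BDF", "Radau")
                                       if m != settings.method]
        sol = None
        for method in methods:
            sol = solve_ivp(self.rhs, t_span, np.asarray(y0, float),
                            method=method, rtol=settings.rtol,
                            atol=settings.atol_vector(),
                            max_step=settings.max_step, t_eval=t_eval,
                            dense_output=False)
            if sol.success:
                return Trajectory(self, sol.t, sol.y.T)
        raise IntegrationError(
            f"integration failed: {sol.message}",
            t_last=sol.t[-1] if len(sol.t) else t_span[0],
            y_last=sol.y[:, -1] if len(sol.t) else np.asarray(y0))

    def run_to_steady(self, y0, max_t=60.0, chunk=2.0,
                      settings: SolverSettings | None = None):
        """Integrate until the relative state velocity falls below the
        steady-state threshold (sustained), or max_t is reached."""
        settings = settings or SolverSettings()
        y = np.asarray(y0, float)
        t = 0.0
        atol = settings.atol_vector()
        while t < max_t:
            traj = self.integrate(y, (0.0, chunk), settings, n_save=5)
            y = traj.Y[-1]
            t += chunk
            dy = self.rhs(t, y)
            rel = np.max(np.abs(dy) / (np.abs(y) + atol * 1e3 + 1e-9))
            if rel < settings.ss_threshold * 60.0:  # threshold per second
                break
        return y, t

    def observe(self, y, t=0.0) -> dict:
        """Derived observables at a state (units in the keys' conventions)."""
        _, ex = self.rhs(t, y, return_extras=True)
        z = (2.303 * 8.314462618 * (273.15 + self.ctx.T)
             / 96485.33212 * 1e3)
        dph_mv = -z * (ex["pH_x"] - self.ctx.pH_e)
        return {
            "dpsi_mV": y[IX["dpsi"]],
            "dpH_mV": dph_mv,
            "pmf_mV": y[IX["dpsi"]] + dph_mv,
            "pH_mtx": ex["pH_x"],
            "MVO2": ex["MVO2"],
            "pct_NADH": 100.0 * ex["NADH_frac"],
            "pct_cred": 100.0 * ex["cred_frac"],
            "V_mtx": ex["V_mtx"],
            "V_ims": ex["V_ims"],
            "Cl_x": ex["Cl_x"],
            "free_Ca_mtx": ex["free_x"]["Ca"],
            "free_Mg_mtx": ex["free_x"]["Mg"],
            "free_Ca_buf": ex["free_e"]["Ca"],
            "fluxes": ex["fluxes"],
            "charge_flux": ex["charge_flux"],
        }


@dataclass
class Trajectory:
    """Saved time course with on-demand algebraic outputs."""

    model: Model
    t: np.ndarray
    Y: np.ndarray

    def observable(self, key) -> np.ndarray:
        return np.array([self.model.observe(y)[key] for y in self.Y])

    def final(self) -> np.ndarray:
        return self.Y[-1]

    def to_dataframe(self):
        import pandas as pd
        from .states import STATE_UNITS
        cols = {f"{n} ({STATE_UNITS[n]})": self.Y[:, i]
                for i, n in enumerate(ODE_STATE_NAMES)}
        df = pd.DataFrame({"t (min)": self.t, **cols})
        return df

    def observables_dataframe(self):
        import pandas as pd
        rows = []
        for ti, y in zip(self.t, self.Y):
            ob = self.model.observe(y, ti)
            ob.pop("fluxes")
            rows.append({"t (min)": ti, **ob})
        return pd.DataFrame(rows)


def default_model(T=25.0, **kw) -> Model:
    """Convenience constructor with shipped parameters."""
    ctx = SimContext(pset=load_parameters(), T=T, **kw)
    return Model(ctx)
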