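"""Executable replicas of the five experimental protocols.

Each protocol bundles a buffer recipe (total salt/substrate/nucleotide/
chelator concentrations, clamped pH, temperature, osmolarity, mitochondrial
load), an initialization mode, and an ordered schedule of timed actions
(species additions, free-ion clamps, parameter surgery such as oligomycin
zeroing the F1FO activity, rate-law variant swaps, recordings).

Initialization standardizes the starting point: the model is simulated from
a condensed, fully oxidized, de-energized canonical state under the
protocol's pre-incubation conditions, for long times in the "equilibrated"
modes or briefly in the "non-equilibrated" ones; energized modes run to a
polarized resting steady state.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .states import IX, N_ODE, BUFFER_METABOLITES, ConservedPools
from .model import Model, SimContext, SolverSettings
from .params import ParameterSet, load_parameters
from .thermo import speciate

__all__ = ["BufferSpec", "Step", "Protocol", "build_initial_state",
           "initialize", "execute", "run_bose", "run_lanoue", "run_wan",
           "run_kowaltowski", "run_devin", "infer_load", "PROTOCOLS"]

log = logging.getLogger("mitodyn.protocols")

INIT_MODES = ("de_energized_equilibrated", "de_energized_nonequilibrated",
              "energized_equilibrated")


@dataclass(frozen=True)
class BufferSpec:
    """Total buffer composition (M), clamped pH, temperature and load."""

    totals: dict = field(default_factory=dict)   # buffer species -> M
    cations: dict = field(default_factory=dict)  # K/Na/Mg/Ca totals -> M
    egta: float = 0.0
    edta: float = 0.0
    pH: float = 7.2
    T: float = 25.0
    osm: float = 0.290       # Osm
    load: float = 1.0        # mg/mL

    def __post_init__(self):
        for k, v in {**self.totals, **self.cations}.items():
            if v < 0:
                raise ValueError(f"negative buffer total for {k}")


@dataclass(frozen=True)
class Step:
    time: float              # minutes from protocol start
    action: str              # add | clamp_free_ca | set_param | khe_variant
    #                        | record | equilibrate
    payload: object = None
    label: str = ""


@dataclass
class Protocol:
    name: str
    buffer: BufferSpec
    init_mode: str
    steps: list = field(default_factory=list)
    init_kwargs: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.init_mode not in INIT_MODES:
            raise ValueError(f"unknown init mode {self.init_mode}")
        times = [s.time for s in self.steps]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("step times must be non-decreasing")


# ---------------------------------------------------------------------------
# canonical matrix composition and state assembly
# ---------------------------------------------------------------------------

#: canonical condensed-matrix metabolite amounts, nmol/mg
CANONICAL_MATRIX = {
    "PYR_x": 0.01, "CoASH_x": 1.5, "AcCoA_x": 0.3, "CIT_x": 0.2,
    "ISOC_x": 0.03, "aKG_x": 0.15, "SCoA_x": 0.1, "SUC_x": 0.5,
    "FUM_x": 0.2, "MAL_x": 0.5, "OAA_x": 0.005, "GLU_x": 4.0, "ASP_x": 4.0,
    "NAD_x": 2.8, "GDP_x": 4.5, "ADP_x": 7.0, "AMP_x": 0.5, "Pi_x": 2.0,
    "UQ_x": 1.2, "cox_i": 0.25,
}

MATRIX_K_MM = 120.0        # initial matrix [K+], mM (125 for the Bose runs)
MATRIX_NA_MM = 5.0
MATRIX_FREE_MG = 0.4e-3    # target initial free Mg2+, M
MATRIX_FREE_CA = 1.0e-7    # target initial free Ca2+, M


def _matrix_mg_ca_totals(pset, v_ref):
    """Total matrix Mg/Ca giving the target free levels at the canonical
    composition (speciating against the matrix Mg/Ca ligands)."""
    lig = {}
    for name, amt in CANONICAL_MATRIX.items():
        base = name[:-2]
        lig[base] = amt / v_ref * 1e-3
    lig["ATP"] = (ConservedPools().ANtot_x - CANONICAL_MATRIX["ADP_x"]
                  - CANONICAL_MATRIX["AMP_x"]) / v_ref * 1e-3
    lig["GTP"] = (ConservedPools().GNtot_x
                  - CANONICAL_MATRIX["GDP_x"]) / v_ref * 1e-3
    keep = ("ATP", "ADP", "AMP", "GTP", "GDP", "Pi", "CIT", "ISOC", "MAL",
            "SUC", "FUM", "aKG")
    lig = {k: v for k, v in lig.items() if k in keep}
    res = speciate(lig, {"K": MATRIX_K_MM * 1e-3, "Na": MATRIX_NA_MM * 1e-3},
                   7.2, fixed_free={"Mg": MATRIX_FREE_MG,
                                    "Ca": MATRIX_FREE_CA})
    mg_tot = MATRIX_FREE_MG + sum(res.bound[(l, "Mg")] for l in lig)
    ca_tot = MATRIX_FREE_CA + sum(res.bound[(l, "Ca")] for l in lig)
    return mg_tot, ca_tot


def build_initial_state(model: Model, buffer: BufferSpec,
                        matrix_k_mM: float = MATRIX_K_MM) -> np.ndarray:
    """Assemble the 65 ODE states for a protocol's starting point."""
    p = model.p
    v_ref = p["general", "V_mtx_ref"]
    v_ims = p["general", "total_water"] - v_ref
    y = np.zeros(N_ODE)
    for name, amt in CANONICAL_MATRIX.items():
        y[IX[name]] = amt
    mg_tot, ca_tot = _matrix_mg_ca_totals(model.p, v_ref)
    y[IX["K_x"]] = matrix_k_mM * 1e-3 * v_ref * 1e3
    y[IX["Na_x"]] = MATRIX_NA_MM * 1e-3 * v_ref * 1e3
    y[IX["Mg_x"]] = mg_tot * v_ref * 1e3
    y[IX["Ca_x"]] = ca_tot * v_ref * 1e3
    y[IX["H_x"]] = model.proton_content_for_ph(buffer.pH, v_ref)

    for name in BUFFER_METABOLITES:
        y[IX[name]] = buffer.totals.get(name[:-2], 0.0)
    for cat in ("K", "Na", "Mg", "Ca"):
        y[IX[f"{cat}_e"]] = buffer.cations.get(cat, 0.0)
    # IMS mirrors the buffer
    for name in BUFFER_METABOLITES:
        base = name[:-2]
        y[IX[base + "_i"]] = y[IX[name]] * v_ims * 1e3
    for cat in ("K", "Na", "Mg", "Ca"):
        y[IX[f"{cat}_i"]] = y[IX[f"{cat}_e"]] * v_ims * 1e3
    y[IX["H_i"]] = model.proton_content_for_ph(buffer.pH, v_ims)
    y[IX["dpsi"]] = 0.0
    return y


def make_model(buffer: BufferSpec, pset: ParameterSet | None = None,
               **ctx_kw) -> Model:
    pset = pset if pset is not None else load_parameters()
    ctx = SimContext(pset=pset, T=buffer.T, pH_e=buffer.pH, osm_e=buffer.osm,
                     load=buffer.load, egta=buffer.egta, edta=buffer.edta,
                     **ctx_kw)
    model = Model(ctx)
    # reference consistency is defined once, at the standard condition
    ref_buffer = replace(buffer, pH=7.2)
    y_ref = build_initial_state_uncalibrated(model, ref_buffer)
    model.calibrate_reference(y_ref)
    return model


def build_initial_state_uncalibrated(model, buffer):
    # same assembly, used before the reference constants exist
    model.n_imp = 0.0
    model.x_imp = 0.0
    return build_initial_state(model, buffer)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

class InitializationError(RuntimeError):
    pass


def initialize(protocol: Protocol, pset: ParameterSet | None = None,
               settings: SolverSettings | None = None):
    """Return (model, state) at the protocol's pre-incubation point."""
    buf = protocol.buffer
    kw = dict(protocol.init_kwargs)
    matrix_k = kw.pop("matrix_k_mM", MATRIX_K_MM)
    init_buffer = kw.pop("init_buffer", buf)
    deplete_pi = kw.pop("deplete_pi", False)
    ctx_kw = {k: v for k, v in kw.items()
              if k in ("clamp_free_ca", "khe_bose")}
    model = make_model(init_buffer, pset, **ctx_kw)
    y = build_initial_state(model, init_buffer, matrix_k_mM=matrix_k)
    settings = settings or SolverSettings()
    log.info("initializing protocol %s (%s)", protocol.name,
             protocol.init_mode)
    if protocol.init_mode == "de_energized_nonequilibrated":
        traj = model.integrate(y, (0.0, 0.5), settings, n_save=5)
        y = traj.final()
    elif protocol.init_mode == "energized_equilibrated":
        # a polarized pre-incubation steady state on the minutes scale the
        # experiments use (the true asymptote would exhaust the buffer ATP)
        y, t_ss = model.run_to_steady(y, max_t=6.0, chunk=2.0,
                                      settings=settings)
        log.info("  energized pre-incubation state after %.1f min", t_ss)
    else:
        y, t_ss = model.run_to_steady(y, max_t=30.0, chunk=3.0,
                                      settings=settings)
        log.info("  pre-incubation steady state after %.1f min", t_ss)
    if deplete_pi:
        # Pi depletion surgery: the matrix, IMS and buffer phosphate pools
        # are emptied, then briefly re-equilibrated
        y[IX["Pi_x"]] = 0.05
        y[IX["Pi_i"]] = 0.0
        y[IX["Pi_e"]] = 0.0
        traj = model.integrate(y, (0.0, 0.5), settings, n_save=5)
        y = traj.final()
    # the working buffer may differ from the initialization buffer
    if init_buffer is not buf:
        for name in BUFFER_METABOLITES:
            base = name[:-2]
            if buf.totals.get(base, 0.0) != init_buffer.totals.get(base, 0.0):
                y[IX[name]] = buf.totals.get(base, 0.0)
        model.ctx = replace(model.ctx, T=buf.T, pH_e=buf.pH, osm_e=buf.osm,
                            load=buf.load, egta=buf.egta, edta=buf.edta)
        from .thermo import TemperatureModel
        import warnings as _w
        tm = TemperatureModel()
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            from .rates import FLUX_NAMES
            model.tf = {r: tm.factor(r, buf.T)
                        for r in FLUX_NAMES + ("TCC", "DCC")}
    return model, y


# ---------------------------------------------------------------------------
# protocol executor
# ---------------------------------------------------------------------------

def execute(protocol: Protocol, pset: ParameterSet | None = None,
            settings: SolverSettings | None = None, n_save=60):
    """Run a protocol schedule; returns dict with records and trajectory.

    Actions: ``add`` {species: delta M}, ``set_param`` {(rxn, sym): value},
    ``clamp_free_ca`` float|None, ``khe_variant`` bool, ``equilibrate``
    max minutes, ``record`` label.
    """
    settings = settings or SolverSettings()
    model, y = initialize(protocol, pset, settings)
    t = 0.0
    records = {}
    times_all, ys_all = [np.array([0.0])], [y[None, :]]
    for step in protocol.steps:
        if step.time > t:
            traj = model.integrate(y, (t, step.time), settings,
                                   n_save=max(int((step.time - t) * 10), 5))
            y = traj.final()
            times_all.append(traj.t)
            ys_all.append(traj.Y)
            t = step.time
        if step.action == "add":
            log.info("t=%.2f min: add %s", t, step.payload)
            for species, delta in step.payload.items():
                y[IX[f"{species}_e"]] += delta
        elif step.action == "set_param":
            log.info("t=%.2f min: set %s", t, step.payload)
            for key, value in step.payload.items():
                model.p[key] = value
        elif step.action == "clamp_free_ca":
            model.ctx = replace(model.ctx, clamp_free_ca=step.payload)
        elif step.action == "khe_variant":
            model.ctx = replace(model.ctx, khe_bose=bool(step.payload))
        elif step.action == "equilibrate":
            y, _ = model.run_to_steady(y, max_t=step.payload,
                                       settings=settings)
        elif step.action == "record":
            records[step.label or f"t{t:g}"] = {
                "t": t, "y": y.copy(), "obs": model.observe(y, t)}
            log.info("t=%.2f min: record %s", t, step.label)
        else:
            raise ValueError(f"unknown protocol action {step.action}")
    return {"model": model, "y": y, "t": t, "records": records,
            "times": np.concatenate(times_all),
            "Y": np.vstack(ys_all)}


# ---------------------------------------------------------------------------
# the five experimental data-set protocols
# ---------------------------------------------------------------------------

def bose_buffer() -> BufferSpec:
    """125 mM KCl, 15 mM NaCl, 20 mM K-Hepes, 1 mM KEGTA, 1 mM K2EDTA,
    5 mM MgCl, 4 uM TPP+ at pH 7.1; 37 C; ~1 mg/mL."""
    return BufferSpec(
        totals={},
        cations={"K": 0.125 + 0.020 + 0.001 + 0.002, "Na": 0.015,
                 "Mg": 0.005, "Ca": 0.0008},
        egta=1e-3, edta=1e-3, pH=7.1, T=37.0, osm=0.300, load=1.0)


def lanoue_buffer() -> BufferSpec:
    """150 mM KCl, 20 mM Tris-Cl, 20 mM KPi, 5 mM MgCl2, 30 mM glucose at
    pH 7.2; 28 C; 3.5 mg/mL."""
    return BufferSpec(
        totals={"Pi": 0.020, "GLC": 0.030},
        cations={"K": 0.150 + 0.020, "Mg": 0.005, "Na": 0.0, "Ca": 1e-6},
        pH=7.2, T=28.0, osm=0.370, load=3.5)


def wan_buffer(nacl=0.005) -> BufferSpec:
    """130 mM KCl, 20 mM HEPES, 5 mM MgCl2, 5 mM ATP, 5 mM KH2PO4, 5 mM
    NaCl, 1 mM EGTA at pH 7.0; 28 C; 2 mg/mL."""
    return BufferSpec(
        totals={"ATP": 0.005, "Pi": 0.005},
        cations={"K": 0.130 + 0.005, "Na": nacl, "Mg": 0.005, "Ca": 2e-5},
        egta=1e-3, pH=7.0, T=28.0, osm=0.300, load=2.0)


def kowaltowski_buffer() -> BufferSpec:
    """135 mM KCl, 5 mM succinate, 2.5 mM Pi, 100 uM EGTA, 0.5 mM MgCl2 at
    pH 7.2; 28 C; 0.1 mg/mL."""
    return BufferSpec(
        totals={"SUC": 0.005, "Pi": 0.0025},
        cations={"K": 0.135, "Mg": 0.0005, "Na": 0.0, "Ca": 1e-6},
        egta=1e-4, pH=7.2, T=28.0, osm=0.290, load=0.1)


def devin_buffer(osm=0.250) -> BufferSpec:
    """KCl set by osmolarity ([K+] = osm/2), 20 mM Tris-HCl, 1 mM EGTA,
    6 mM Tris-glutamate, 6 mM Tris-malate, 5 mM Tris-Pi at pH 7.2; 26 C;
    0.1 mg/mL (adjusted load)."""
    return BufferSpec(
        totals={"GLU": 0.006, "MAL": 0.006, "Pi": 0.005},
        cations={"K": osm / 2.0, "Na": 0.0, "Mg": 1e-6, "Ca": 1e-7},
        egta=1e-3, pH=7.2, T=26.0, osm=osm, load=0.1)


def infer_load(substrate_conc_M: float, chamber_volume_mL: float,
               content_nmol_per_mg: float) -> float:
    """Mitochondrial load (mg/mL) implied by a total substrate content.

    A 5 mM substrate in a 1 mL chamber equalling 1430 nmol/mg of protein
    implies 5e-3 * 1e6 / 1430 = 3.5 mg/mL.
    """
    total_nmol = substrate_conc_M * chamber_volume_mL * 1e6
    return total_nmol / content_nmol_per_mg / chamber_volume_mL


# -- Bose -------------------------------------------------------------------

def run_bose(pi_levels=(0.0, 1e-3, 3e-3, 10e-3), state=3,
             pset=None, settings=None, bose_khe=True):
    """Pi titration on glutamate/malate-energized, Pi-depleted mitochondria.

    Sequence per Pi level: 60 s after glutamate/malate, 60 s after Pi, and
    (state 3) 30 s after 1.3 mM ADP.  Free Ca2+ is clamped at 550 nM.
    Returns one observable record per Pi level.
    """
    buf = bose_buffer()
    results = {}
    proto_init = Protocol(
        name="bose-init", buffer=buf, init_mode="de_energized_equilibrated",
        init_kwargs={"matrix_k_mM": 125.0 if bose_khe else MATRIX_K_MM,
                     "deplete_pi": True, "clamp_free_ca": 550e-9,
                     "khe_bose": bose_khe,
                     "init_buffer": replace(buf, totals={"ATP": 1e-3})})
    settings = settings or SolverSettings()
    model0, y0 = initialize(proto_init, pset, settings)
    for pi in pi_levels:
        model = make_model(buf, pset if pset is not None else None,
                           clamp_free_ca=550e-9, khe_bose=bose_khe)
        model.n_imp, model.x_imp = model0.n_imp, model0.x_imp
        y = y0.copy()
        y[IX["GLU_e"]] += 5e-3
        y[IX["MAL_e"]] += 5e-3
        traj = model.integrate(y, (0.0, 1.0), settings, n_save=8)
        y = traj.final()
        y[IX["Pi_e"]] += pi
        traj = model.integrate(y, (1.0, 2.0), settings, n_save=8)
        y = traj.final()
        if state == 3:
            y[IX["ADP_e"]] += 1.3e-3
            traj = model.integrate(y, (2.0, 2.5), settings, n_save=6)
            y = traj.final()
        results[pi] = model.observe(y)
    return results


# -- LaNoue -----------------------------------------------------------------

def run_lanoue(substrates="pyr_mal", state=2, t_end=8.0,
               pset=None, settings=None, n_save=40):
    """TCA intermediate dynamics; returns a trajectory with observables.

    substrates: "pyr_mal" (2 mM pyruvate + 5 mM malate), "pyr" (1 mM
    pyruvate) or None.  State 3 adds 0.5 mM ADP with the 30 mM glucose
    hexokinase trap regenerating it.
    """
    buf = lanoue_buffer()
    proto = Protocol(name="lanoue", buffer=buf,
                     init_mode="de_energized_nonequilibrated")
    settings = settings or SolverSettings()
    model, y = initialize(proto, pset, settings)
    if substrates == "pyr_mal":
        y[IX["PYR_e"]] += 2e-3
        y[IX["MAL_e"]] += 5e-3
    elif substrates == "pyr":
        y[IX["PYR_e"]] += 1e-3
    if state == 3:
        y[IX["ADP_e"]] += 0.5e-3
    traj = model.integrate(y, (0.0, t_end), settings, n_save=n_save)
    return traj


def run_lanoue_akg_curve(malate_levels=(0.0, 1e-3, 2.5e-3, 5e-3),
                         pset=None, settings=None, t_end=6.0):
    """Steady extra-mitochondrial alpha-ketoglutarate vs added malate
    (state 2, 2 mM pyruvate)."""
    buf = lanoue_buffer()
    settings = settings or SolverSettings()
    out = {}
    proto = Protocol(name="lanoue", buffer=buf,
                     init_mode="de_energized_nonequilibrated")
    model0, y0 = initialize(proto, pset, settings)
    for mal in malate_levels:
        model = make_model(buf, pset)
        model.n_imp, model.x_imp = model0.n_imp, model0.x_imp
        y = y0.copy()
        y[IX["PYR_e"]] += 2e-3
        y[IX["MAL_e"]] += mal
        traj = model.integrate(y, (0.0, t_end), settings, n_save=10)
        out[mal] = float(traj.final()[IX["aKG_e"]])
    return out


# -- Wan --------------------------------------------------------------------

def run_wan(ca_levels=(0.5e-6, 1e-6, 2e-6), na_mM=5.0,
            pset=None, settings=None, t_run=2.0):
    """Steady matrix free Ca2+ versus extra-mitochondrial free Ca2+.

    ca_levels are free buffer Ca2+ set points (clamped via the EGTA
    system); returns {free Ca_e: steady matrix free Ca2+} after an
    ATP-energized initialization and a 2-minute loading simulation.
    """
    buf = wan_buffer(nacl=na_mM * 1e-3)
    proto = Protocol(name="wan", buffer=buf,
                     init_mode="energized_equilibrated")
    settings = settings or SolverSettings()
    model0, y0 = initialize(proto, pset, settings)
    out = {}
    for ca in ca_levels:
        model = make_model(buf, pset, clamp_free_ca=ca)
        model.n_imp, model.x_imp = model0.n_imp, model0.x_imp
        y = y0.copy()
        traj = model.integrate(y, (0.0, t_run), settings, n_save=8)
        obs = model.observe(traj.final())
        out[ca] = obs["free_Ca_mtx"]
    return out


def wan_ca_cycle_fraction(ca_free=550e-9, na_mM=5.0, adp=1e-3, pset=None,
                          settings=None, t_run=3.0):
    """Percent of the ETS proton efflux dissipated by Na+/Ca2+ cycling.

    Runs the Wan ionic conditions with glutamate/malate so the ETS is
    active, clamps buffer free Ca2+ at a titration-level set point, and at
    steady state compares the proton-equivalent cost of the
    CaUNI/mNCE/mNHE cycle (2 charges per Ca2+ taken up, 1 net charge per
    mNCE turnover, 1 proton per mNHE turnover) against the total proton
    efflux pumped by complexes I, III and IV.
    """
    buf = wan_buffer(nacl=na_mM * 1e-3)
    extra = {"GLU": 0.005, "MAL": 0.005}
    if adp:
        extra["ADP"] = adp          # phosphorylating (state 3) respiration
    buf = replace(buf, totals={**buf.totals, **extra})
    proto = Protocol(name="wan-respiring", buffer=buf,
                     init_mode="energized_equilibrated",
                     init_kwargs={"clamp_free_ca": ca_free})
    settings = settings or SolverSettings()
    model, y = initialize(proto, pset, settings)
    traj = model.integrate(y, (0.0, t_run), settings, n_save=6)
    y = traj.final()
    fl = model.observe(y)["fluxes"]
    ets_h = 4.0 * fl["CI"] + 4.0 * fl["CIII"] + 2.0 * fl["CIV"]
    ca_cost = 2.0 * fl["CaUNI"] + fl["mNCE"] + max(fl["mNHE"], 0.0)
    return 100.0 * ca_cost / max(ets_h, 1e-12), fl


def wan_resting_state(pset=None, settings=None):
    """ATP-energized resting steady state (no respiratory substrate)."""
    proto = Protocol(name="wan", buffer=wan_buffer(),
                     init_mode="energized_equilibrated")
    model, y = initialize(proto, pset, settings or SolverSettings())
    return model, y


# -- Kowaltowski ------------------------------------------------------------

KOWALTOWSKI_CONDITIONS = {
    # condition -> (ATP M, ADP M, oligomycin, diazoxide, fivehd)
    "atp_oligo": (200e-6, 0.0, True, False, False),
    "atp_adp": (200e-6, 1e-3, False, False, False),
    "atp_oligo_adp": (200e-6, 1e-3, True, False, False),
    "noatp_oligo": (0.0, 0.0, True, False, False),
    "atp_adp_dzx": (200e-6, 1e-3, False, True, False),
    "atp_adp_dzx_5hd": (200e-6, 1e-3, False, True, True),
    "atp_oligo_dzx": (200e-6, 0.0, True, True, False),
    "atp_oligo_dzx_5hd": (200e-6, 0.0, True, True, True),
}


def run_kowaltowski(condition="atp_oligo", t_end=10.0, pset=None,
                    settings=None, n_save=50):
    """Succinate-energized swelling; returns the volume trajectory.

    Pharmacology is parameter surgery: oligomycin zeroes the F1FO activity,
    diazoxide zeroes the endogenous mKATP inhibition, 5-HD zeroes the mKATP
    conductance.
    """
    atp, adp, oligo, dzx, fivehd = KOWALTOWSKI_CONDITIONS[condition]
    buf = kowaltowski_buffer()
    init_buf = replace(buf, totals={"Pi": 0.0025})   # pre-energization
    steps = []
    surgery = {}
    if oligo:
        surgery[("F1FO", "V")] = 0.0
    if dzx:
        surgery[("mKATP", "rho_endo")] = 0.0
    if fivehd:
        surgery[("mKATP", "g")] = 0.0
    if surgery:
        steps.append(Step(0.0, "set_param", surgery))
    proto = Protocol(name="kowaltowski", buffer=buf,
                     init_mode="de_energized_nonequilibrated",
                     init_kwargs={"init_buffer": init_buf})
    settings = settings or SolverSettings()
    pset_run = (pset if pset is not None else load_parameters()).copy()
    model, y = initialize(replace(proto), pset_run, settings)
    for key, value in surgery.items():
        model.p[key] = value
    if atp:
        y[IX["ATP_e"]] += atp
    if adp:
        y[IX["ADP_e"]] += adp
    traj = model.integrate(y, (0.0, t_end), settings, n_save=n_save)
    return traj


# -- Devin ------------------------------------------------------------------

def run_devin(osm_levels=(0.150, 0.250, 0.350, 0.450), state=3,
              pset=None, settings=None):
    """Bioenergetic observables versus buffer osmolarity.

    State 2: 5-minute run to steady state on glutamate/malate; state 3 then
    adds 1 mM ADP for a 10-minute pseudo-steady state.  The adenylate
    kinase reaction is off (no divalent cation in the medium).
    """
    settings = settings or SolverSettings()
    out = {}
    for osm in osm_levels:
        buf = devin_buffer(osm)
        pset_run = (pset if pset is not None else load_parameters()).copy()
        pset_run["AK", "Vf"] = 1e-12
        proto = Protocol(name="devin", buffer=buf,
                         init_mode="energized_equilibrated")
        model, y = initialize(proto, pset_run, settings)
        traj = model.integrate(y, (0.0, 5.0), settings, n_save=10)
        y = traj.final()
        obs2 = model.observe(y)
        if state == 3:
            y[IX["ADP_e"]] += 1e-3
            traj = model.integrate(y, (0.0, 10.0), settings, n_save=15)
            y = traj.final()
        out[osm] = {"state2": obs2, "final": model.observe(y)}
    return out


PROTOCOLS = {
    "bose": run_bose,
    "lanoue": run_lanoue,
    "wan": run_wan,
    "kowaltowski": run_kowaltowski,
    "devin": run_devin,
}
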