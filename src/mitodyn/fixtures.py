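"""Packaged protocol files and small synthetic data curves.

The five protocol recipes ship with the package as versioned YAML files
(one per experimental data set).  ``generate_fixtures`` copies them to a
working directory and adds small synthetic data curves simulated from the
shipped parameters plus Gaussian noise, for exercising the fitting
harness; regeneration under a fixed seed is bit-identical.
"""

from __future__ import annotations

import shutil
from importlib import resources
from pathlib import Path

import numpy as np

from .calibrate import DataCurve, DataSet
from .params import load_parameters

__all__ = ["generate_fixtures", "toy_datasets", "toy_simulator",
           "sensitivity_conditions", "protocol_file", "TOY_KEYS"]

PROTOCOL_NAMES = ("bose", "lanoue", "wan", "kowaltowski", "devin")


def protocol_file(name: str):
    """Path-like handle on a shipped protocol YAML."""
    if name not in PROTOCOL_NAMES:
        raise KeyError(name)
    return resources.files("mitodyn.data.protocols").joinpath(f"{name}.yaml")


# ---------------------------------------------------------------------------
# toy fitting problem: isolated pyruvate-dehydrogenase rate curves
# (the tier-2 style calibration setting: fit a rate expression to its own
# titration data)
# ---------------------------------------------------------------------------

TOY_KEYS = (("PDH", "Vmax"), ("PDH", "Km_PYR"), ("PDH", "Km_NAD"))

_PYR_GRID = np.array([5e-6, 2e-5, 5e-5, 1e-4, 3e-4, 1e-3])
_NAD_GRID = np.array([1e-5, 3e-5, 1e-4, 3e-4, 1e-3, 3e-3])


def _pdh_rate(pset, pyr, nad):
    """PDH initial rate at saturating CoASH, zero products, full
    activation (the assay condition of an isolated-enzyme titration)."""
    from .rates import RateContext, tca_fluxes
    base = {"PYR": pyr, "CoASH": 2e-3, "AcCoA": 0.0, "CIT": 0.0,
            "ISOC": 0.0, "aKG": 0.0, "SCoA": 0.0, "SUC": 0.0, "FUM": 0.0,
            "MAL": 0.0, "OAA": 0.0, "GLU": 0.0, "ASP": 0.0, "NAD": nad,
            "NADH": 0.0, "GDP": 0.0, "GTP": 0.0, "ADP": 1e-3, "ATP": 1e-6,
            "AMP": 0.0, "Pi": 2e-3, "UQ": 1e-3, "UQH2": 0.0}
    tf = {r: 1.0 for r in ("PDH", "CS", "ACH", "IDH", "aKGDH", "SCoAS",
                           "SDH", "FH", "MDH", "NDK", "GOT")}
    ctx = RateContext(cx=base, ci={}, ce={},
                      fx={"H": 1e-8, "K": 0.12, "Na": 5e-3, "Mg": 4e-4,
                          "Ca": 1e-4},
                      fi={"H": 1e-7}, fe={"H": 1e-7},
                      tf=tf, p=pset)
    return tca_fluxes(ctx)["PDH"]


def toy_simulator(pset, curve):
    """Predict PDH titration points; curve abscissa indexes the grid."""
    if curve.observable == "J_PDH_vs_PYR":
        return np.array([_pdh_rate(pset, pyr, 2e-3) for pyr in _PYR_GRID])
    if curve.observable == "J_PDH_vs_NAD":
        return np.array([_pdh_rate(pset, 2e-3, nad) for nad in _NAD_GRID])
    raise KeyError(curve.observable)


def toy_datasets(seed=0, pset=None, noise=0.05):
    """Synthetic PDH titration curves simulated from the shipped parameter
    values with multiplicative Gaussian noise.  Returns (data_sets, keys)
    where keys are the three adjustable parameters the curves identify."""
    pset = pset if pset is not None else load_parameters()
    rng = np.random.default_rng(seed)
    curves = []
    for obs, grid in (("J_PDH_vs_PYR", _PYR_GRID),
                      ("J_PDH_vs_NAD", _NAD_GRID)):
        probe = DataCurve(curve_id=obs, observable=obs, abscissa=grid,
                          values=np.zeros_like(grid))
        y = toy_simulator(pset, probe)
        noisy = y * (1.0 + noise * rng.standard_normal(y.shape))
        curves.append(DataCurve(curve_id=obs, observable=obs, abscissa=grid,
                                values=noisy, sigma=np.abs(y) * noise))
    return [DataSet(name="pdh_titration", curves=curves)], list(TOY_KEYS)


# ---------------------------------------------------------------------------
# sensitivity conditions
# ---------------------------------------------------------------------------

def sensitivity_conditions(protocol="lanoue", t_end=1.5, n_time=5,
                           rtol=1e-6):
    """Callables mapping a ParameterSet to a (n_time, 73) output array.

    Each callable replays one experimental condition with tightened solver
    tolerances and samples all 73 states at equally spaced time points.
    The default replays the TCA-dynamics protocol in state 2 and state 3
    (heavy mitochondrial load, so every subsystem turns over quickly).
    """
    from .model import SolverSettings
    from .states import StateVector, unpack_state, ALL_STATE_NAMES

    settings = SolverSettings(rtol=rtol, atol_matrix=1e-12,
                              atol_other=1e-9)

    def make(state):
        def run(pset):
            from .protocols import run_lanoue
            traj = run_lanoue(substrates="pyr_mal", state=state,
                              t_end=t_end, pset=pset, settings=settings,
                              n_save=n_time + 1)
            rows = []
            for k in range(1, n_time + 1):
                y = traj.Y[k]
                _, ex = traj.model.rhs(traj.t[k], y, return_extras=True)
                sv = StateVector(y, traj.model.ctx.pools)
                full = unpack_state(sv, algebraic={
                    "V_mtx": ex["V_mtx"], "V_ims": ex["V_ims"],
                    "Cl_x": ex["Cl_x"]})
                rows.append([full[n] for n in ALL_STATE_NAMES])
            return np.asarray(rows)
        return run

    return [make(2), make(3)]


# ---------------------------------------------------------------------------
# fixture emission
# ---------------------------------------------------------------------------

def generate_fixtures(out_dir, seed=0):
    """Emit the five protocol YAMLs plus toy CSV data curves."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in PROTOCOL_NAMES:
        dst = out / f"{name}.yaml"
        with resources.as_file(protocol_file(name)) as src:
            shutil.copyfile(src, dst)
        paths.append(dst)
    data_sets, _ = toy_datasets(seed=seed)
    import pandas as pd
    for ds in data_sets:
        for curve in ds.curves:
            dst = out / f"toy_{ds.name}_{curve.curve_id}.csv"
            pd.DataFrame({
                "abscissa (M)": curve.abscissa,
                f"{curve.observable} (nmol/min/mg)": curve.values,
                "sigma (nmol/min/mg)": curve.sigma,
            }).to_csv(dst, index=False)
            paths.append(dst)
    return paths
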