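"""Weighted-least-squares objective, local sensitivity analysis, fitting.

Objective
---------
f(p) = sum_k (1/M_k) sum_j (1/N_jk) sum_i ((y_ijk - Y_ijk)/sigma_ijk)^2
over data sets k, curves j and points i.  Missing standard deviations are
imputed as a 7.5% relative error (midpoint of the 5-10% convention).

Local sensitivity
-----------------
The absolute normalized local sensitivity coefficient of parameter l is the
average over experimental conditions, five equally spaced time points and
all 73 states of |(dy/dp_l) * (p_l / y)|, approximated by a centered finite
difference with a 1% relative perturbation, integrated at strict solver
tolerances.  Where |y| falls below the state's absolute tolerance the
normalization is floored there and the entry is flagged below-resolution.

Fitting
-------
Simulated-annealing global search over the adjustable parameters (log-scale
Gaussian moves, geometric cooling) followed by a local Nelder-Mead polish;
failed simulations score a large finite penalty so the annealer can
traverse bad regions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .params import ParameterSet

__all__ = ["DataCurve", "DataSet", "objective", "LSCReport",
           "local_sensitivity", "fit", "FitResult", "PENALTY",
           "impute_sigma"]

log = logging.getLogger("mitodyn.calibrate")

PENALTY = 1.0e6
_SIGMA_REL = 0.075      # imputed relative error (within the 5-10% band)


@dataclass
class DataCurve:
    """One experimental curve: abscissa (time or titration value),
    observable id, values and standard deviations."""

    curve_id: str
    observable: str
    abscissa: np.ndarray
    values: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self):
        self.abscissa = np.asarray(self.abscissa, float)
        self.values = np.asarray(self.values, float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, float)

    @property
    def n_points(self):
        return len(self.values)


@dataclass
class DataSet:
    name: str
    curves: list = field(default_factory=list)

    @property
    def n_curves(self):
        return len(self.curves)


def impute_sigma(curve: DataCurve) -> np.ndarray:
    """Per-point sigma with the relative-error imputation applied."""
    base = np.abs(curve.values) * _SIGMA_REL
    base = np.where(base > 0, base, _SIGMA_REL)
    if curve.sigma is None:
        return base
    sig = np.asarray(curve.sigma, float).copy()
    bad = ~np.isfinite(sig) | (sig <= 0)
    sig[bad] = base[bad]
    return sig


def objective(pset: ParameterSet, data_sets, simulator) -> float:
    """Evaluate the weighted-least-squares objective at a parameter point.

    ``simulator(pset, curve)`` must return the model predictions aligned
    with ``curve.abscissa``; any exception it raises is scored with the
    large finite penalty (plus the exception is logged), so optimization
    can continue through pathological parameter regions.
    """
    f = 0.0
    for ds in data_sets:
        if ds.n_curves == 0:
            continue
        acc = 0.0
        for curve in ds.curves:
            try:
                y = np.asarray(simulator(pset, curve), float)
            except Exception as exc:          # noqa: BLE001
                log.warning("simulation failed for %s/%s: %s",
                            ds.name, curve.curve_id, exc)
                return PENALTY
            sig = impute_sigma(curve)
            resid = (y - curve.values) / sig
            acc += float(np.sum(resid ** 2)) / curve.n_points
        f += acc / ds.n_curves
    return f


# ---------------------------------------------------------------------------
# local sensitivity
# ---------------------------------------------------------------------------

@dataclass
class LSCReport:
    values: dict                     # parameter key -> LSC (dimensionless)
    below_resolution: set
    settings: dict

    def mean(self):
        return float(np.mean(list(self.values.values())))

    def variance(self):
        return float(np.var(list(self.values.values())))

    def ranked(self):
        return sorted(self.values.items(), key=lambda kv: -kv[1])

    def to_dataframe(self):
        import pandas as pd
        rows = [{"reaction": k[0], "symbol": k[1], "LSC": v,
                 "below_resolution": k in self.below_resolution}
                for k, v in self.ranked()]
        return pd.DataFrame(rows)


def local_sensitivity(pset: ParameterSet, conditions, keys=None,
                      rel_step: float = 0.01, floor: float = 1e-9,
                      n_time: int = 5) -> LSCReport:
    """Centered-finite-difference LSCs averaged over states, time points
    and conditions.

    ``conditions`` is a list of callables; each maps a ParameterSet to an
    array of model outputs with shape (n_time, n_states) sampled at
    equally spaced time points.  ``keys`` defaults to every parameter in
    the set.
    """
    keys = list(keys if keys is not None else pset.params.keys())
    base = {}
    for k, cond in enumerate(conditions):
        y = np.asarray(cond(pset), float)
        base[k] = y
    values = {}
    below = set()
    for key in keys:
        p0 = pset[key]
        if p0 == 0.0:
            values[key] = 0.0
            below.add(key)
            continue
        h = rel_step * abs(p0)
        acc = 0.0
        n_acc = 0
        flagged = False
        for k, cond in enumerate(conditions):
            pset[key] = p0 + h
            try:
                y_hi = np.asarray(cond(pset), float)
                pset[key] = p0 - h
                y_lo = np.asarray(cond(pset), float)
            finally:
                pset[key] = p0
            dy = (y_hi - y_lo) / (2.0 * h)
            denom = np.abs(base[k])
            small = denom < floor
            if np.any(small & (np.abs(y_hi - y_lo) > 0)):
                flagged = True
            denom = np.maximum(denom, floor)
            acc += float(np.sum(np.abs(dy) * abs(p0) / denom)
                         / base[k].size)
            n_acc += 1
        values[key] = acc / max(n_acc, 1)
        if flagged:
            below.add(key)
    return LSCReport(values=values, below_resolution=below,
                     settings={"rel_step": rel_step, "n_time": n_time,
                               "n_conditions": len(conditions),
                               "floor": floor})


# ---------------------------------------------------------------------------
# fitting: simulated annealing + local polish
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    best_params: ParameterSet
    best_f: float
    initial_f: float
    trace: list
    budget_exhausted: bool = False


def fit(pset: ParameterSet, keys, bounds, data_sets, simulator,
        seed: int = 0, budget: int = 200, t0: float = 1.0,
        cooling: float = 0.97, polish: bool = True) -> FitResult:
    """Anneal-then-polish parameter estimation over ``keys``.

    bounds: {key: (lo, hi)}, all positive.  The annealer proposes
    log-normal single-parameter moves with Metropolis acceptance and
    geometric cooling; the polish stage is a Nelder-Mead refinement in
    log-parameter space.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    keys = list(keys)
    for k in keys:
        lo, hi = bounds[k]
        if not (0 < lo <= pset[k] <= hi):
            raise ValueError(f"start value for {k} outside bounds")

    work = pset.copy()
    f_cur = objective(work, data_sets, simulator)
    f_init = f_cur
    best = work.copy()
    f_best = f_cur
    trace = [(0, f_cur, f_best)]
    temp = t0 * max(f_cur, 1.0)
    for it in range(1, budget + 1):
        key = keys[rng.integers(len(keys))]
        old = work[key]
        lo, hi = bounds[key]
        prop = old * math.exp(rng.normal(0.0, 0.15))
        prop = min(max(prop, lo), hi)
        work[key] = prop
        f_new = objective(work, data_sets, simulator)
        accept = (f_new <= f_cur
                  or rng.random() < math.exp(-(f_new - f_cur)
                                             / max(temp, 1e-12)))
        if accept:
            f_cur = f_new
            if f_new < f_best:
                f_best = f_new
                best = work.copy()
        else:
            work[key] = old
        temp *= cooling
        trace.append((it, f_cur, f_best))
    if polish and keys:
        from scipy.optimize import minimize

        def fun(logp):
            trial = best.copy()
            for k, lp in zip(keys, logp):
                lo, hi = bounds[k]
                trial[k] = min(max(math.exp(lp), lo), hi)
            return objective(trial, data_sets, simulator)

        x0 = np.log([best[k] for k in keys])
        res = minimize(fun, x0, method="Nelder-Mead",
                       options={"maxiter": max(40 * len(keys), 120),
                                "xatol": 1e-4, "fatol": 1e-10})
        if res.fun < f_best:
            f_best = float(res.fun)
            for k, lp in zip(keys, res.x):
                lo, hi = bounds[k]
                best[k] = min(max(math.exp(lp), lo), hi)
    exhausted = f_best >= f_init and budget > 0
    if exhausted:
        log.warning("fit budget exhausted without improvement; returning "
                    "best-so-far")
    return FitResult(best_params=best, best_f=f_best, initial_f=f_init,
                     trace=trace, budget_exhausted=exhausted)
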