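"""Hybrid global/local parameter estimation against time-series datasets.

The cost is a max-normalized, sd-weighted least squares over all
observations,

    Phi(p) = sum_ij ( (y_i(t_j) - yhat_i(t_j, p)) / (max_j y_i(t_j) * sd_ij) )^2,

so observables on different scales contribute comparably; sd defaults to 1
where the data carry no replicate spread.  Estimation proceeds in stages
mirroring the model's modular structure (bio-distribution -> NF-kB core ->
cytokines/CD70 -> T-cell K_4), each stage running Latin hypercube starts
through a derivative-free coordinate pattern search followed by
bound-constrained quasi-Newton refinement of the best solutions.  Rate
constants are searched in log10 space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import qmc

from .datasets import Dataset, _KIND_SPEC
from .model import SimulationError, builtin_scenarios, simulate
from .parameters import PARAM_GROUPS, DesignConstants, ParameterSet

__all__ = [
    "cost_function", "predict_dataset", "model_cost",
    "lhs_sample", "pattern_search", "global_search", "local_refine",
    "CalibrationStage", "CalibrationPlan", "default_plan",
    "OptimizationResult", "CalibrationError", "calibrate",
]


class CalibrationError(RuntimeError):
    """A stage failed; carries the results of the stages that completed."""

    def __init__(self, message: str, completed: dict):
        super().__init__(message)
        self.completed = completed


# ---------------------------------------------------------------------------
# cost
# ---------------------------------------------------------------------------

def cost_function(datasets: Dataset | Sequence[Dataset],
                  predictions: np.ndarray | Sequence[np.ndarray]) -> float:
    """Max-normalized, sd-weighted sum of squared residuals.

    ``predictions`` must align row-wise with each dataset's frame.  Rows
    without replicate spread (sd missing or 0) get unit weight.  A dataset
    whose per-observable maximum is 0 cannot be normalized and raises.
    """
    if isinstance(datasets, Dataset):
        datasets = [datasets]
        predictions = [np.asarray(predictions, float)]
    else:
        predictions = [np.asarray(p, float) for p in predictions]
    total = 0.0
    for ds, yhat in zip(datasets, predictions):
        f = ds.frame
        if yhat.shape != (len(f),):
            raise ValueError("prediction length must match dataset rows")
        y = f["value"].to_numpy(float)
        sd = f["sd"].to_numpy(float)
        for obs, idx in f.groupby("observable").groups.items():
            sel = f.index.get_indexer(idx)
            ymax = np.max(np.abs(y[sel]))
            if ymax == 0:
                raise ZeroDivisionError(
                    f"observable {obs!r} has max value 0; cannot normalize")
            # sd below numerical noise counts as absent -> unit weight.
            # Valid sds are moderated: the per-observable relative sd is
            # pooled (median CV) and values are floored at 1% of the
            # observable maximum, so small-sample sd estimates and
            # near-zero curve tails cannot dominate the fit.
            valid = np.isfinite(sd[sel]) & (sd[sel] > 1e-9 * ymax)
            if valid.any():
                yfloor = np.maximum(np.abs(y[sel]), 0.01 * ymax)
                cv = np.median(sd[sel][valid] / yfloor[valid])
                w = np.where(valid, cv * yfloor, 1.0)
            else:
                w = np.ones(sel.size)
            r = (y[sel] - yhat[sel]) / (ymax * w)
            total += float(np.sum(r * r))
    return total


def predict_dataset(dataset: Dataset, params: ParameterSet,
                    constants: DesignConstants = DesignConstants()
                    ) -> np.ndarray:
    """Model predictions aligned with a dataset's rows.

    Simulates the dataset kind's scenario per arm on a dense grid covering
    the observation times and interpolates; max-normalized observables are
    scaled by the simulated maximum over the observed times, matching the
    normalization applied to the data.
    """
    spec = _KIND_SPEC[dataset.kind]
    var_of = dict(spec["observables"])
    f = dataset.frame
    out = np.empty(len(f))
    if dataset.kind == "biodistribution":
        return _predict_biodistribution(dataset, params, constants)
    scen_all = builtin_scenarios()
    for arm, scenario_name in spec["arms"].items():
        rows = f["arm"] == arm
        if not rows.any():
            continue
        times = f.loc[rows, "time_h"].to_numpy(float)
        grid = np.union1d([0.0], times)
        traj = simulate(scen_all[scenario_name], params, constants, grid=grid)
        for obs in f.loc[rows, "observable"].unique():
            sel = rows & (f["observable"] == obs)
            t_obs = f.loc[sel, "time_h"].to_numpy(float)
            yhat = np.interp(t_obs, traj.time, traj[var_of[obs]])
            if dataset.max_normalized:
                scale = float(np.max(yhat))
                yhat = yhat / scale if scale > 0 else yhat
            out[sel.to_numpy()] = yhat
    return out


def _predict_biodistribution(dataset: Dataset, params: ParameterSet,
                             constants: DesignConstants) -> np.ndarray:
    """Fast path: the organ block is a linear constant-coefficient ODE, so
    each organ curve has a closed form (difference of exponentials)."""
    f = dataset.frame
    lam = (params["mu_BS"] + params["mu_BLu"] + params["mu_BLi"]
           + params["mu"])
    b0 = constants.DC_in / params["Q_Blood"]
    q_b = params["Q_Blood"]

    def organ_curve(t, mu_in, mu_out, q):
        a = mu_in * (q_b / q) * b0
        if mu_out == 0.0:
            # terminal reservoir
            return (a / lam) * (1.0 - np.exp(-lam * t)) if lam > 0 \
                else a * t
        if abs(lam - mu_out) < 1e-12 * max(lam, mu_out, 1e-12):
            return a * t * np.exp(-lam * t)
        return a * (np.exp(-mu_out * t) - np.exp(-lam * t)) / (lam - mu_out)

    curves = {
        "dc_blood": lambda t: q_b * b0 * np.exp(-lam * t),
        "dc_lung": lambda t: params["Q_Lung"] * organ_curve(
            t, params["mu_BLu"], params["mu_Lu0"], params["Q_Lung"]),
        "dc_liver": lambda t: params["Q_Liver"] * organ_curve(
            t, params["mu_BLi"], 0.0, params["Q_Liver"]),
        "dc_spleen": lambda t: params["Q_Spleen"] * organ_curve(
            t, params["mu_BS"], params["mu_S0"], params["Q_Spleen"]),
    }
    out = np.empty(len(f))
    for obs in f["observable"].unique():
        sel = (f["observable"] == obs).to_numpy()
        t_obs = f.loc[sel, "time_h"].to_numpy(float)
        out[sel] = curves[obs](t_obs)
    return out


def model_cost(datasets: Sequence[Dataset], params: ParameterSet,
               constants: DesignConstants = DesignConstants()) -> float:
    """Phi evaluated by simulating the model for each dataset."""
    preds = [predict_dataset(ds, params, constants) for ds in datasets]
    return cost_function(list(datasets), preds)


# ---------------------------------------------------------------------------
# samplers and optimizers
# ---------------------------------------------------------------------------

def lhs_sample(n: int, bounds: Sequence[tuple[float, float]],
               seed: int = 0) -> np.ndarray:
    """Latin hypercube sample: per dimension exactly one point falls in each
    of the n equal-probability strata."""
    if n < 1:
        raise ValueError("n must be >= 1")
    lo = np.array([b[0] for b in bounds], float)
    hi = np.array([b[1] for b in bounds], float)
    if np.any(lo > hi) or not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
        raise ValueError("bounds must be finite with lower <= upper")
    u = qmc.LatinHypercube(d=len(bounds), seed=seed).random(n)
    return lo + u * (hi - lo)


def pattern_search(f: Callable[[np.ndarray], float], x0: np.ndarray,
                   bounds: Sequence[tuple[float, float]],
                   budget: int = 2000, mesh0: float = 0.25,
                   mesh_tol: float = 1e-6) -> tuple[np.ndarray, float, int]:
    """Bound-constrained coordinate pattern search (mesh halving on failure,
    doubling on success).  Returns (x_best, f_best, n_evals)."""
    lo = np.array([b[0] for b in bounds], float)
    hi = np.array([b[1] for b in bounds], float)
    span = hi - lo
    x = np.clip(np.asarray(x0, float), lo, hi)
    fx = f(x)
    nev = 1
    if not np.isfinite(fx):
        raise FloatingPointError("objective not finite at start")
    mesh = mesh0
    d = x.size
    while mesh > mesh_tol and nev < budget:
        improved = False
        for i in range(d):
            if span[i] == 0:
                continue
            for sgn in (+1.0, -1.0):
                xt = x.copy()
                xt[i] = np.clip(x[i] + sgn * mesh * span[i], lo[i], hi[i])
                if xt[i] == x[i]:
                    continue
                ft = f(xt)
                nev += 1
                if np.isfinite(ft) and ft < fx:
                    x, fx = xt, ft
                    improved = True
                    break
                if nev >= budget:
                    break
            if nev >= budget:
                break
        mesh = min(2.0 * mesh, 0.5) if improved else 0.5 * mesh
    return x, fx, nev


def global_search(objective: Callable[[np.ndarray], float],
                  starts: np.ndarray,
                  bounds: Sequence[tuple[float, float]],
                  budget_per_start: int = 2000,
                  top_k: int | None = None) -> list[tuple[np.ndarray, float]]:
    """Pattern search from every start; solutions ranked by cost.

    Starts where the objective is non-finite are marked failed (cost inf)
    rather than aborting the whole search.
    """
    solutions = []
    for x0 in np.atleast_2d(starts):
        try:
            x, fx, _ = pattern_search(objective, x0, bounds,
                                      budget=budget_per_start)
        except FloatingPointError:
            solutions.append((np.asarray(x0, float), np.inf))
            continue
        solutions.append((x, fx))
    solutions.sort(key=lambda s: s[1])
    return solutions[:top_k] if top_k else solutions


def local_refine(objective: Callable[[np.ndarray], float],
                 starts: Sequence[tuple[np.ndarray, float]],
                 bounds: Sequence[tuple[float, float]],
                 polish: bool = True) -> list[tuple[np.ndarray, float]]:
    """Local refinement of ranked starts: bound-constrained quasi-Newton
    (finite-difference gradients) followed by a simplex polish.

    The quasi-Newton step can stall in the narrow curved valleys these
    sd-weighted least-squares surfaces develop; the Nelder-Mead polish
    (also bound-constrained) reliably slides along them.  Refinement never
    worsens a start: if the local steps end higher, the start is kept.
    Raises only if every refinement fails.
    """
    if len(starts) == 0:
        raise ValueError("need at least one start")
    refined = []
    failures = []
    for x0, f0 in starts:
        x_best, f_best = np.asarray(x0, float), float(f0)
        try:
            res = minimize(objective, x_best, method="L-BFGS-B", bounds=bounds,
                           options={"maxiter": 200})
            if np.isfinite(res.fun) and res.fun < f_best:
                x_best, f_best = np.asarray(res.x, float), float(res.fun)
            if polish:
                res = minimize(objective, x_best, method="Nelder-Mead",
                               bounds=bounds,
                               options={"maxfev": 250 * len(x_best),
                                        "fatol": 1e-12, "xatol": 1e-8})
                if np.isfinite(res.fun) and res.fun < f_best:
                    x_best, f_best = np.asarray(res.x, float), float(res.fun)
        except Exception as exc:  # pragma: no cover - solver internals
            failures.append(str(exc))
        refined.append((x_best, f_best))
    if len(failures) == len(starts):
        raise CalibrationError("all local refinements failed: "
                               + "; ".join(failures), {})
    refined.sort(key=lambda s: s[1])
    return refined


# ---------------------------------------------------------------------------
# staged calibration
# ---------------------------------------------------------------------------

_STAGE_FREE: dict[str, list[str]] = {
    "biodistribution": ["mu_BS", "mu_BLu", "mu_BLi", "mu", "mu_S0", "mu_Lu0"],
    "nfkb": list(PARAM_GROUPS["upstream"]) + list(PARAM_GROUPS["ikk"])
            + list(PARAM_GROUPS["nfkb"]),
    "cytokine": list(PARAM_GROUPS["il8"]) + list(PARAM_GROUPS["il6"])
                + list(PARAM_GROUPS["il12"]) + list(PARAM_GROUPS["cd70"]),
    "tcell": ["K_4"],
}


@dataclass
class CalibrationStage:
    name: str
    kinds: tuple[str, ...]
    free: tuple[str, ...]
    log_scale: bool = True


@dataclass
class CalibrationPlan:
    """Ordered stages; each stage's best estimates are fixed before the next.

    The final stage frees exactly one parameter, the Michaelis constant of
    T-cell activation (K_4).
    """

    stages: list[CalibrationStage]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for st in self.stages:
            overlap = seen & set(st.free)
            if overlap:
                raise ValueError(f"stage {st.name!r} re-frees {sorted(overlap)}")
            seen |= set(st.free)
        last = self.stages[-1]
        if last.name == "tcell" and tuple(last.free) != ("K_4",):
            raise ValueError("the T-cell stage frees exactly K_4")


def default_plan() -> CalibrationPlan:
    return CalibrationPlan(stages=[
        CalibrationStage("biodistribution", ("biodistribution",),
                         tuple(_STAGE_FREE["biodistribution"])),
        CalibrationStage("nfkb", ("nfkb",), tuple(_STAGE_FREE["nfkb"])),
        CalibrationStage("cytokine", ("cytokine",),
                         tuple(_STAGE_FREE["cytokine"])),
        CalibrationStage("tcell", ("tcell",), tuple(_STAGE_FREE["tcell"])),
    ])


@dataclass
class OptimizationResult:
    """Solution archive of one calibration stage."""

    free_names: list[str]
    starts: np.ndarray                      # (n_starts, d) in search space
    solutions: list[tuple[np.ndarray, float]]   # global, ranked
    refined: list[tuple[np.ndarray, float]]     # local, ranked
    seed: int
    log_scale: bool = True

    @property
    def best(self) -> tuple[np.ndarray, float]:
        return self.refined[0]

    def top_values(self, k: int = 100) -> np.ndarray:
        """Top-k global solutions mapped back to natural parameter scale,
        shape (k, d)."""
        xs = np.array([x for x, _ in self.solutions[:k]])
        return 10.0 ** xs if self.log_scale else xs

    def best_values(self, k: int = 15) -> np.ndarray:
        xs = np.array([x for x, _ in self.refined[:k]])
        return 10.0 ** xs if self.log_scale else xs

    def best_params(self, template: ParameterSet) -> ParameterSet:
        vec = self.best[0]
        vals = 10.0 ** vec if self.log_scale else vec
        return template.with_overrides(dict(zip(self.free_names, vals)))


def _stage_bounds(stage: CalibrationStage, params: ParameterSet
                  ) -> list[tuple[float, float]]:
    bounds = []
    for name in stage.free:
        lo = params.lower.get(name, 1e-4)
        hi = params.upper.get(name, 1e2)
        if stage.log_scale:
            lo = np.log10(max(lo, 1e-12))
            hi = np.log10(hi)
        bounds.append((lo, hi))
    return bounds


def calibrate(plan: CalibrationPlan, datasets: Mapping[str, Dataset],
              params: ParameterSet,
              constants: DesignConstants = DesignConstants(),
              seed: int = 0, n_starts: int = 1000, top_global: int = 100,
              n_refine: int | None = None, budget_per_start: int = 2000
              ) -> dict[str, OptimizationResult]:
    """Run the staged hybrid estimation.

    Per stage: ``n_starts`` LHS starts -> pattern search -> keep the
    ``top_global`` solutions -> locally refine them (``n_refine`` limits
    how many, default all); the stage's best estimate is fixed before the
    next stage.  The best-15 refined solutions feed the downstream
    identifiability analysis.  A stage failure aborts subsequent stages,
    raising with the completed archive attached.
    """
    results: dict[str, OptimizationResult] = {}
    current = params
    for si, stage in enumerate(plan.stages):
        missing = [k for k in stage.kinds if k not in datasets]
        if missing:
            raise CalibrationError(
                f"stage {stage.name!r} lacks datasets {missing}", results)
        ds = [datasets[k] for k in stage.kinds]
        bounds = _stage_bounds(stage, current)

        def objective(x, _stage=stage, _ds=ds, _params=current):
            vals = 10.0 ** x if _stage.log_scale else x
            trial = _params.with_overrides(dict(zip(_stage.free, vals)))
            try:
                return model_cost(_ds, trial, constants)
            except (SimulationError, FloatingPointError, ZeroDivisionError):
                return np.inf

        starts = lhs_sample(n_starts, bounds, seed=seed + si)
        sols = global_search(objective, starts, bounds,
                             budget_per_start=budget_per_start)
        if not np.isfinite(sols[0][1]):
            raise CalibrationError(
                f"stage {stage.name!r}: no finite-cost solution", results)
        n_ref = top_global if n_refine is None else n_refine
        refined = local_refine(objective, sols[:min(n_ref, len(sols))], bounds)
        res = OptimizationResult(free_names=list(stage.free), starts=starts,
                                 solutions=sols[:top_global], refined=refined,
                                 seed=seed + si, log_scale=stage.log_scale)
        results[stage.name] = res
        current = res.best_params(current)
    return results
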