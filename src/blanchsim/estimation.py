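"""Losses and inverse parameter estimation.

The estimation workflow mirrors common practice in kinetic modelling:

* model predictions are linearly interpolated to the measurement times
  (no silent extrapolation);
* the goodness-of-fit is either the pooled RMSE over all points or a
  multi-experiment L2 in which each experiment contributes its *mean*
  squared error, so densely sampled experiments do not dominate;
* fitting is bounded quasi-Newton (L-BFGS-B) with rate constants optimized
  on a log scale, optionally from multiple starts, or — for ill-conditioned
  multi-parameter problems — cyclic coordinate descent with golden-section
  line searches and a relative-improvement stopping rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.interpolate import interp1d
from scipy.optimize import minimize

from .errors import ExtrapolationError, FitError, ValidationError

__all__ = [
    "Dataset",
    "FreeParameter",
    "FitSpec",
    "FitResult",
    "interpolate_prediction",
    "rmse",
    "weighted_l2",
    "fit_parameters",
    "cyclic_coordinate_fit",
]

OBSERVABLES = {
    "activity_pod",
    "activity_lox",
    "activity_pme",
    "firmness",
    "temperature",
    "tau_qualitative",
    "leaching_metric",
}


@dataclass
class Dataset:
    """Observed records plus the per-experiment conditions.

    ``records`` columns: ``experiment_id``, ``observable``, ``time_s``,
    ``value``.  ``conditions`` maps experiment ids to whatever the forward
    model needs (a bath program, a constant temperature, ...).  ``metadata``
    carries provenance; synthetic generators embed their ground truth here.
    """

    records: pd.DataFrame
    conditions: dict = dc_field(default_factory=dict)
    metadata: dict = dc_field(default_factory=dict)

    REQUIRED = ("experiment_id", "observable", "time_s", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValidationError(f"dataset records missing columns {missing}")
        if (self.records["time_s"] < 0).any():
            raise ValidationError("observation times must be >= 0")
        unknown = set(self.records["observable"]) - OBSERVABLES
        if unknown:
            raise ValidationError(f"unknown observables {sorted(unknown)}")
        bounded = self.records["observable"].str.startswith("activity") | (
            self.records["observable"] == "firmness"
        )
        vals = self.records.loc[bounded, "value"]
        if ((vals < 0) | (vals > 1.2)).any():
            raise ValidationError(
                "activity/firmness observations must lie in [0, 1.2]"
            )

    def experiments(self) -> list:
        return list(dict.fromkeys(self.records["experiment_id"]))

    def slice(self, experiment_id) -> pd.DataFrame:
        return self.records[self.records["experiment_id"] == experiment_id]

    def observations(self, observable: str | None = None) -> dict:
        """Mapping experiment_id -> (times, values), optionally filtered."""
        df = self.records
        if observable is not None:
            df = df[df["observable"] == observable]
        out = {}
        # sorted by experiment and time so losses are invariant to row order
        for eid, grp in df.groupby("experiment_id", sort=True):
            grp = grp.sort_values("time_s", kind="stable")
            out[eid] = (grp["time_s"].to_numpy(float), grp["value"].to_numpy(float))
        return out

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def interpolate_prediction(pred_times, pred_values, obs_times) -> np.ndarray:
    """Linear interpolation of the prediction to observation times.

    Raises :class:`ExtrapolationError` when an observation falls outside
    the predicted range.
    """
    pred_times = np.asarray(pred_times, dtype=float)
    obs_times = np.asarray(obs_times, dtype=float)
    if obs_times.size and (
        obs_times.min() < pred_times[0] - 1e-9 or obs_times.max() > pred_times[-1] + 1e-9
    ):
        raise ExtrapolationError(
            f"observation times [{obs_times.min():g}, {obs_times.max():g}] outside "
            f"prediction range [{pred_times[0]:g}, {pred_times[-1]:g}]"
        )
    f = interp1d(pred_times, np.asarray(pred_values, dtype=float), assume_sorted=True)
    return f(np.clip(obs_times, pred_times[0], pred_times[-1]))


def rmse(obs_times, obs_values, pred_times, pred_values) -> float:
    """Pooled root-mean-square error with interpolated predictions."""
    obs_values = np.asarray(obs_values, dtype=float)
    if obs_values.size == 0:
        raise ValidationError("empty observation slice")
    yhat = interpolate_prediction(pred_times, pred_values, obs_times)
    return float(np.sqrt(np.mean((obs_values - yhat) ** 2)))


def weighted_l2(observations: dict, predictions: dict, mode: str = "mean") -> float:
    """Multi-experiment L2 norm.

    ``mode='mean'`` (default): each experiment contributes its mean squared
    error, weighting experiments equally regardless of sampling density.
    ``mode='sum'``: each experiment contributes its raw sum of squares
    (dense experiments weigh more).
    """
    if mode not in ("mean", "sum"):
        raise ValidationError("weighted_l2 mode must be 'mean' or 'sum'")
    total = 0.0
    for eid, (t_obs, y_obs) in observations.items():
        y_obs = np.asarray(y_obs, dtype=float)
        if y_obs.size == 0:
            raise ValidationError(f"experiment {eid!r} has no observations")
        t_pred, y_pred = predictions[eid]
        yhat = interpolate_prediction(t_pred, y_pred, t_obs)
        ss = float(np.sum((y_obs - yhat) ** 2))
        total += ss / y_obs.size if mode == "mean" else ss
    return total


# ---------------------------------------------------------------------------
# Fit specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FreeParameter:
    """A parameter to estimate: bounds are mandatory, rates use log scale."""

    name: str
    initial: float
    lower: float
    upper: float
    log_scale: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite([self.lower, self.upper, self.initial]).all():
            raise ValidationError(f"{self.name}: bounds and initial must be finite")
        if not self.lower < self.upper:
            raise ValidationError(f"{self.name}: lower bound must be < upper bound")
        if not self.lower <= self.initial <= self.upper:
            raise ValidationError(f"{self.name}: initial value outside bounds")
        if self.log_scale and self.lower <= 0:
            raise ValidationError(f"{self.name}: log scale requires positive bounds")

    # internal optimization coordinate: the parameter mapped to [0, 1]
    # (log10 scale for rates), so finite-difference steps and line-search
    # tolerances are comparable across parameters of any magnitude
    def encode(self, x: float) -> float:
        if self.log_scale:
            lo, hi = np.log10(self.lower), np.log10(self.upper)
            return (np.log10(x) - lo) / (hi - lo)
        return (x - self.lower) / (self.upper - self.lower)

    def decode(self, z: float) -> float:
        if self.log_scale:
            lo, hi = np.log10(self.lower), np.log10(self.upper)
            return 10.0 ** (lo + z * (hi - lo))
        return self.lower + z * (self.upper - self.lower)


@dataclass
class FitSpec:
    """What to fit and how.

    ``loss`` is ``weighted_l2`` (per-experiment mean squared errors summed)
    or ``pooled_rmse`` (squared, pooled over all points); ``tolerance`` is
    the relative function-value convergence tolerance of the quasi-Newton
    solver and the floor used by the coordinate-descent stopping rule.
    """

    free: list[FreeParameter]
    fixed: dict = dc_field(default_factory=dict)
    loss: str = "weighted_l2"
    method: str = "bounded_quasi_newton"
    tolerance: float = 1e-4
    multistart: int = 1
    seed: int = 0
    cycle_tol: float = 0.005
    max_cycles: int = 40
    l2_mode: str = "mean"

    def __post_init__(self) -> None:
        if self.loss not in ("weighted_l2", "pooled_rmse"):
            raise ValidationError(f"unknown loss '{self.loss}'")
        if self.method not in ("bounded_quasi_newton", "cyclic_coordinate"):
            raise ValidationError(f"unknown method '{self.method}'")
        names = [p.name for p in self.free]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate free-parameter names")


@dataclass
class FitResult:
    """Estimated parameters with diagnostics."""

    params: dict
    loss: float
    residuals: dict
    converged: bool
    n_iterations: int
    multistart: list = dc_field(default_factory=list)
    flags: list = dc_field(default_factory=list)

    def __getitem__(self, name: str) -> float:
        return self.params[name]


def _make_objective(spec: FitSpec, dataset: Dataset, forward, observable):
    obs = dataset.observations(observable)
    if not obs:
        raise ValidationError("no observations for the requested observable")
    n_total = sum(len(v[1]) for v in obs.values())

    def loss_of(params: dict) -> tuple[float, dict]:
        preds = forward(params)
        residuals = {}
        for eid, (t_obs, y_obs) in obs.items():
            t_pred, y_pred = preds[eid]
            yhat = interpolate_prediction(t_pred, y_pred, t_obs)
            residuals[eid] = np.asarray(y_obs) - yhat
        if spec.loss == "weighted_l2":
            val = sum(
                float(np.sum(r**2)) / (r.size if spec.l2_mode == "mean" else 1)
                for r in residuals.values()
            )
        else:  # pooled_rmse (squared; same minimizer, smooth)
            val = sum(float(np.sum(r**2)) for r in residuals.values()) / n_total
        return val, residuals

    def assemble(z: np.ndarray) -> dict:
        params = dict(spec.fixed)
        for p, zi in zip(spec.free, z):
            params[p.name] = p.decode(zi)
        return params

    def f(z: np.ndarray) -> float:
        return loss_of(assemble(z))[0]

    return loss_of, assemble, f


def _starts(spec: FitSpec) -> list[np.ndarray]:
    z0 = np.array([p.encode(p.initial) for p in spec.free])
    starts = [z0]
    if spec.multistart > 1:
        rng = np.random.default_rng(spec.seed)
        lo = np.array([p.encode(p.lower) for p in spec.free])
        hi = np.array([p.encode(p.upper) for p in spec.free])
        for _ in range(spec.multistart - 1):
            starts.append(lo + rng.random(lo.size) * (hi - lo))
    return starts


def fit_parameters(
    spec: FitSpec, dataset: Dataset, forward, observable: str | None = None
) -> FitResult:
    """Bounded quasi-Newton (L-BFGS-B) minimization of the chosen loss.

    ``forward`` maps a parameter dict to ``{experiment_id: (times, values)}``
    prediction series.  Log-scaled parameters are optimized in log10 space.
    Deterministic given the spec (multistart draws use ``spec.seed``).
    """
    loss_of, assemble, f = _make_objective(spec, dataset, forward, observable)
    bounds = [(p.encode(p.lower), p.encode(p.upper)) for p in spec.free]
    table = []
    best = None
    for z0 in _starts(spec):
        f0 = f(z0)
        if not np.isfinite(f0):
            raise FitError("non-finite loss at the initial point")
        # scipy's ftol compares improvements against max(|f|, 1), i.e. it is
        # absolute for small losses; the convergence criterion here is
        # *relative*, so restart the solver until one restart improves the
        # loss by less than `tolerance` relative to its value
        res = None
        z_cur, f_prev, nit = z0, f0, 0
        for _ in range(12):
            step = minimize(
                f,
                z_cur,
                method="L-BFGS-B",
                bounds=bounds,
                options={"ftol": 1e-13, "maxiter": 500},
            )
            nit += int(step.nit)
            res = step if res is None or step.fun <= res.fun else res
            rel = (f_prev - step.fun) / max(abs(f_prev), 1e-300)
            z_cur, f_prev = step.x, float(step.fun)
            if rel < spec.tolerance or f_prev == 0.0:
                break
        table.append(
            {"start_loss": f0, "final_loss": float(res.fun), "converged": bool(res.success),
             "n_iterations": nit}
        )
        res.nit = nit
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not any(row["converged"] for row in table):
        if best is None:
            raise FitError("no optimization start available")
    params = assemble(best.x)
    loss_val, residuals = loss_of(params)
    return FitResult(
        params=params,
        loss=loss_val,
        residuals=residuals,
        converged=bool(best.success),
        n_iterations=int(best.nit),
        multistart=table,
    )


def _golden_section(f, lo: float, hi: float, tol: float, max_iter: int = 80):
    """Golden-section minimization of a 1-D function on [lo, hi]."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(max_iter):
        if b - a <= tol:
            break
        if fc <= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return (c, fc) if fc <= fd else (d, fd)


def cyclic_coordinate_fit(
    spec: FitSpec, dataset: Dataset, forward, observable: str | None = None
) -> FitResult:
    """Cyclic coordinate descent with golden-section line searches.

    Parameters are minimized one at a time, in the declared order, each by a
    golden-section search within its bounds; cycles repeat until the
    relative loss improvement over a full cycle drops below
    ``spec.cycle_tol`` (default 0.5 %) or ``spec.max_cycles`` is reached.
    """
    loss_of, assemble, f = _make_objective(spec, dataset, forward, observable)
    z = np.array([p.encode(p.initial) for p in spec.free])
    bounds = [(p.encode(p.lower), p.encode(p.upper)) for p in spec.free]
    current = f(z)
    if not np.isfinite(current):
        raise FitError("non-finite loss at the initial point")
    start_loss = current
    flags: list[str] = []
    n_cycles = 0
    for cycle in range(spec.max_cycles):
        before = current
        for j, (lo, hi) in enumerate(bounds):
            def f_j(zj, j=j):
                z_trial = z.copy()
                z_trial[j] = zj
                return f(z_trial)

            tol_j = 1e-4 * (hi - lo)
            zj_best, fj_best = _golden_section(f_j, lo, hi, tol_j)
            if fj_best < current:
                z[j] = zj_best
                current = fj_best
        n_cycles = cycle + 1
        if cycle == 0 and current >= before and before > spec.tolerance:
            flags.append("non_improving_first_cycle")
        if before <= 0 or (before - current) / before < spec.cycle_tol:
            break
    params = assemble(z)
    loss_val, residuals = loss_of(params)
    return FitResult(
        params=params,
        loss=loss_val,
        residuals=residuals,
        converged=n_cycles < spec.max_cycles,
        n_iterations=n_cycles,
        multistart=[{"start_loss": start_loss, "final_loss": loss_val,
                     "converged": n_cycles < spec.max_cycles, "n_iterations": n_cycles}],
        flags=flags,
    )
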