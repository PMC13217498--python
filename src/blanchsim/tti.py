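"""Equivalent-time analysis (time-temperature integration).

For a first-order reaction with Arrhenius temperature dependence, the
effect of an arbitrary temperature history T(t) equals the effect of
holding the product at a reference temperature for the *equivalent time*

    t_eff = int exp[ dEa/R * (1/T_ref - 1/T(t)) ] dt.

With matching activation energy, -ln(residual activity) = k_ref * t_eff
exactly, which is what makes an enzyme with first-order kinetics usable as
a time-temperature integrator (TTI) of blanching intensity.  The module
also calibrates the qualitative color-development test (reaction time tau
inversely proportional to residual activity) and searches for the
activation energy that best linearizes a quality attribute against t_eff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConfigError, FitError, ValidationError
from .kinetics import GAS_CONSTANT, _EXP_CLIP

__all__ = [
    "TTIParameters",
    "CalibrationResult",
    "equivalent_time",
    "equivalent_time_series",
    "tti_intensity",
    "calibrate_qualitative_pod",
    "optimize_tti_energy",
]


@dataclass(frozen=True)
class TTIParameters:
    """Activation energy and reference temperature of the integrator."""

    activation_energy: float        # J mol^-1
    t_ref: float                    # K
    k_ref: float | None = None      # s^-1, needed only for the intensity

    def __post_init__(self) -> None:
        if self.t_ref <= 0:
            raise ValidationError("t_ref must be > 0 (kelvin)")

    def lethality(self, temperature_k):
        """Instantaneous weight exp[dEa/R (1/T_ref - 1/T)]."""
        t = np.asarray(temperature_k, dtype=float)
        if np.any(t <= 0):
            raise ValidationError("temperature must be > 0 K")
        expo = (self.activation_energy / GAS_CONSTANT) * (1.0 / self.t_ref - 1.0 / t)
        return np.exp(np.clip(expo, -_EXP_CLIP, _EXP_CLIP))


def _check_history(times, temps_k):
    times = np.asarray(times, dtype=float)
    temps = np.asarray(temps_k, dtype=float)
    if times.size == 0:
        raise ValidationError("empty temperature history")
    if times.shape != temps.shape or times.ndim != 1:
        raise ValidationError("history must be matching 1-D arrays")
    if times.size > 1 and np.any(np.diff(times) <= 0):
        raise ValidationError("history times must be strictly increasing")
    return times, temps


def equivalent_time(times, temperatures_k, tti: TTIParameters) -> float:
    """Equivalent time at ``tti.t_ref`` of the history, s (trapezoid rule)."""
    times, temps = _check_history(times, temperatures_k)
    return float(np.trapezoid(tti.lethality(temps), times))


def equivalent_time_series(times, temperatures_k, tti: TTIParameters) -> np.ndarray:
    """Running equivalent time at each history time."""
    from scipy.integrate import cumulative_trapezoid

    times, temps = _check_history(times, temperatures_k)
    return cumulative_trapezoid(tti.lethality(temps), times, initial=0.0)


def tti_intensity(tti: TTIParameters, teff: float) -> float:
    """Dimensionless treatment intensity k_ref * t_eff."""
    if tti.k_ref is None:
        raise ConfigError("tti_intensity requires k_ref on the TTI parameters")
    return tti.k_ref * teff


@dataclass(frozen=True)
class CalibrationResult:
    """Linear map fitted by ordinary least squares."""

    slope: float
    intercept: float
    r_squared: float
    n: int

    def predict_activity(self, tau):
        """Residual activity predicted from a reaction time, clamped to [0,1]."""
        return np.clip(self.slope / np.asarray(tau, dtype=float) + self.intercept, 0.0, 1.0)


def calibrate_qualitative_pod(activities, taus) -> CalibrationResult:
    """Regress residual activity on the inverse color-development time.

    The qualitative test reports the time tau until visible color develops;
    tau is taken inversely proportional to residual activity, so an OLS fit
    of activity on 1/tau calibrates the test against the quantitative assay.
    """
    a = np.asarray(activities, dtype=float)
    tau = np.asarray(taus, dtype=float)
    if a.shape != tau.shape or a.ndim != 1:
        raise ValidationError("activities and taus must be matching 1-D arrays")
    if a.size < 3:
        raise ValidationError("need at least 3 calibration pairs")
    if np.any(tau <= 0):
        raise ValidationError("reaction times must be > 0")
    inv = 1.0 / tau
    if np.ptp(inv) < 1e-12 * max(np.max(np.abs(inv)), 1.0):
        raise FitError("degenerate spread in 1/tau; regression is rank-deficient")
    res = stats.linregress(inv, a)
    return CalibrationResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=a.size,
    )


def _r_squared_for_energy(
    energy: float,
    quality: np.ndarray,
    histories: list[tuple[np.ndarray, np.ndarray]],
    t_ref: float,
    log_response: bool,
) -> float:
    tti = TTIParameters(energy, t_ref)
    teff = np.array([equivalent_time(t, temp, tti) for t, temp in histories])
    if np.ptp(teff) < 1e-12 * max(np.max(np.abs(teff)), 1.0):
        return 0.0
    y = np.log(quality) if log_response else quality
    res = stats.linregress(teff, y)
    return float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0


def optimize_tti_energy(
    quality,
    histories,
    t_ref: float,
    energy_bounds: tuple[float, float] = (20e3, 600e3),
    grid_points: int = 59,
    log_response: bool = False,
    flat_r2_threshold: float = 0.05,
) -> tuple[float, float, bool]:
    """Activation energy that best linearizes quality against t_eff.

    Scans a uniform grid over ``energy_bounds`` (J/mol), then refines around
    the best grid point by golden-section search; ties break toward the
    smaller energy.  Returns ``(energy, r_squared, flat)`` where ``flat``
    flags an essentially temperature-independent response (max r^2 below
    ``flat_r2_threshold``).

    ``histories`` is a sequence of ``(times_s, temperatures_K)`` pairs, one
    per quality observation.
    """
    q = np.asarray(quality, dtype=float)
    histories = [(np.asarray(t, float), np.asarray(tk, float)) for t, tk in histories]
    if q.size < 4:
        raise ValidationError("need at least 4 quality observations")
    if len(histories) != q.size:
        raise ValidationError("one temperature history per quality value required")
    profiles = {(tuple(t), tuple(tk)) for t, tk in histories}
    if len(profiles) < 2:
        raise FitError("all temperature histories identical; energy unidentifiable")
    if log_response and np.any(q <= 0):
        raise ValidationError("log response requires strictly positive quality values")

    grid = np.linspace(energy_bounds[0], energy_bounds[1], grid_points)
    r2 = np.array(
        [_r_squared_for_energy(e, q, histories, t_ref, log_response) for e in grid]
    )
    best = int(np.argmax(r2))  # argmax takes the first (smallest-energy) tie
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, grid_points - 1)]

    # golden-section refinement of the (negated) r^2 within [lo, hi]
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc = -_r_squared_for_energy(c, q, histories, t_ref, log_response)
    fd = -_r_squared_for_energy(d, q, histories, t_ref, log_response)
    for _ in range(60):
        if b - a < 1e-6 * max(abs(a), abs(b), 1.0):
            break
        if fc <= fd:  # <=: prefer the smaller energy on ties
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = -_r_squared_for_energy(c, q, histories, t_ref, log_response)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = -_r_squared_for_energy(d, q, histories, t_ref, log_response)
    e_star = c if fc <= fd else d
    r2_star = _r_squared_for_energy(e_star, q, histories, t_ref, log_response)
    if r2_star < r2[best]:
        e_star, r2_star = float(grid[best]), float(r2[best])
    flat = r2_star < flat_r2_threshold
    return float(e_star), float(r2_star), flat
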