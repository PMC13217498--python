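"""Synthetic datasets with known ground truth.

Every estimation and TTI routine in the package consumes tabular
(time, condition, value) records; this module generates all of those shapes
from the packaged forward models so the whole fit pipeline can be exercised
end to end without any measured data:

* isothermal extract-inactivation curves (enzyme follows the bath exactly);
* whole-bean residual activities, firmness curves and volume-averaged
  temperature logs from the coupled simulation;
* qualitative color-test reaction times tau = c / activity;
* leaching metrics linear in the equivalent time.

Noise is multiplicative Gaussian (assay errors scale with signal), applied
once per dataset from a mandatory seed, and truncated below at zero.  The
generating parameters are embedded in ``Dataset.metadata`` so recovery
tests can close the loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coupled import simulate_blanching
from .errors import ValidationError
from .estimation import Dataset
from .kinetics import InactivationModel, PectinParameters, residual_activity
from .params import CELSIUS_OFFSET
from .thermal import BathProgram, Composition, CylinderGeometry
from .tti import TTIParameters

__all__ = ["NoiseModel", "gen_isothermal_activity", "gen_blanching_dataset"]


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative Gaussian noise: y -> max(y * (1 + sigma*eps), 0)."""

    kind: str = "multiplicative_gaussian"
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "multiplicative_gaussian"):
            raise ValidationError(f"unknown noise kind '{self.kind}'")
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")

    @classmethod
    def none(cls) -> "NoiseModel":
        return cls(kind="none")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.kind == "none" or self.sigma == 0.0:
            return values.copy()
        noisy = values * (1.0 + self.sigma * rng.standard_normal(values.shape))
        return np.maximum(noisy, 0.0)


def _constant_history(temp_c: float, times: np.ndarray):
    """Two-point constant-temperature history covering the sample times."""
    t_end = float(times.max()) if times.size else 1.0
    grid = np.unique(np.concatenate(([0.0], times, [t_end])))
    temps = np.full_like(grid, temp_c + CELSIUS_OFFSET)
    return grid, temps


def gen_isothermal_activity(
    model: InactivationModel,
    temperatures_c,
    times_s,
    noise: NoiseModel | None = None,
    observable: str = "activity_lox",
) -> Dataset:
    """Isothermal extract-inactivation curves, one experiment per bath.

    Activities are exact (closed-form first-order decay at constant
    temperature, evaluated through the same quadrature path as the rest of
    the package — exact here because the rate is constant), then noised.
    """
    temps = np.asarray(temperatures_c, dtype=float)
    times = np.asarray(times_s, dtype=float)
    if temps.size == 0 or times.size == 0:
        raise ValidationError("temperatures and times must be non-empty")
    if np.any(times < 0):
        raise ValidationError("sample times must be >= 0")
    noise = noise or NoiseModel.none()
    rng = np.random.default_rng(noise.seed)
    rows = []
    for tc in temps:
        grid, grid_k = _constant_history(tc, times)
        act = residual_activity(model, grid, grid_k)
        clean = np.interp(times, grid, act)
        noisy = noise.apply(clean, rng)
        eid = f"iso_{tc:g}C"
        for t, v in zip(times, noisy):
            rows.append((eid, observable, float(t), float(v)))
    records = pd.DataFrame(rows, columns=["experiment_id", "observable", "time_s", "value"])
    conditions = {f"iso_{tc:g}C": float(tc) for tc in temps}
    return Dataset(
        records=records,
        conditions=conditions,
        metadata={"truth": {"model": model}, "noise": noise, "kind": "isothermal"},
    )


def gen_blanching_dataset(
    geometry: CylinderGeometry,
    composition: Composition,
    baths: dict[str, BathProgram],
    sample_times,
    enzymes: dict[str, InactivationModel] | None = None,
    pectin: PectinParameters | None = None,
    noise: NoiseModel | None = None,
    include_temperature: bool = False,
    tau_scale: float | None = None,
    tau_enzyme: str = "pod",
    leaching: tuple[float, float, TTIParameters] | None = None,
) -> Dataset:
    """Whole-bean datasets from the coupled simulation.

    Per bath program the coupled model yields volume-averaged residual
    activities (``activity_<enzyme>`` rows), normalized firmness when
    ``pectin`` is given, and optionally the averaged temperature log.  With
    ``tau_scale`` = c, qualitative reaction times tau = c / activity of
    ``tau_enzyme`` are emitted; with ``leaching`` = (a, b, tti), a leaching
    metric a + b * t_eff is generated per sampling time.  Noise applies to
    every emitted observable.
    """
    sample_times = np.asarray(sample_times, dtype=float)
    if np.any(sample_times < 0):
        raise ValidationError("sample times must be >= 0")
    noise = noise or NoiseModel.none()
    rng = np.random.default_rng(noise.seed)
    tti_map = {"leach": leaching[2]} if leaching else None
    rows = []
    truth: dict = {"enzymes": enzymes, "pectin": pectin}
    for eid, bath in baths.items():
        res = simulate_blanching(
            geometry, composition, bath, enzymes=enzymes, pectin=pectin, tti=tti_map
        )
        for name in enzymes or {}:
            clean = res.at_times(res.average_activities[name], sample_times)
            noisy = noise.apply(clean, rng)
            for t, v in zip(sample_times, noisy):
                rows.append((eid, f"activity_{name}", float(t), float(min(v, 1.2))))
            if tau_scale is not None and name == tau_enzyme:
                taus = noise.apply(tau_scale / np.maximum(clean, 1e-12), rng)
                for t, v in zip(sample_times, taus):
                    rows.append((eid, "tau_qualitative", float(t), float(v)))
        if pectin is not None:
            clean = res.at_times(res.average_firmness, sample_times)
            noisy = noise.apply(clean, rng)
            for t, v in zip(sample_times, noisy):
                rows.append((eid, "firmness", float(t), float(min(v, 1.2))))
        if include_temperature:
            temps = noise.apply(res.at_times(res.average_temperature(), sample_times), rng)
            for t, v in zip(sample_times, temps):
                rows.append((eid, "temperature", float(t), float(v)))
        if leaching is not None:
            a, b, _ = leaching
            teff = res.at_times(res.teff["leach"], sample_times)
            metric = noise.apply(a + b * teff, rng)
            for t, v in zip(sample_times, metric):
                rows.append((eid, "leaching_metric", float(t), float(v)))
    if leaching is not None:
        truth["leaching"] = {"intercept": leaching[0], "slope": leaching[1],
                             "tti": leaching[2]}
    if tau_scale is not None:
        truth["tau_scale"] = tau_scale
    records = pd.DataFrame(rows, columns=["experiment_id", "observable", "time_s", "value"])
    return Dataset(
        records=records,
        conditions=dict(baths),
        metadata={"truth": truth, "noise": noise, "kind": "blanching",
                  "geometry": geometry, "composition": composition},
    )
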