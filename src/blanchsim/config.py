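"""Schema-validated run configuration (YAML/JSON).

Every CLI command reads a :class:`RunConfig` (or one of its blocks).
Unknown keys are rejected with the offending key named, defaults are
resolved at load time, and the resolved configuration round-trips through
``dump`` unchanged so it can be echoed into outputs for provenance.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError as PydanticError

from .errors import ConfigError
from .kinetics import (
    ArrheniusRate,
    BiphasicInactivation,
    MonophasicInactivation,
    PectinParameters,
)
from .params import CELSIUS_OFFSET
from .thermal import BathProgram, BathSegment, Composition, CylinderGeometry

__all__ = ["RunConfig", "load_config", "dump_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryBlock(_Strict):
    radius_m: float = 4.5e-3
    n_cells: int = 5

    def build(self) -> CylinderGeometry:
        return CylinderGeometry(self.radius_m, self.n_cells)


class CompositionBlock(_Strict):
    water: float = 0.90
    carbohydrate: float = 0.07
    protein: float = 0.02
    ash: float = 0.006
    fat: float | None = None

    def build(self) -> Composition:
        return Composition(self.water, self.carbohydrate, self.protein, self.ash, self.fat)


class SegmentBlock(_Strict):
    duration_s: float
    temperature_c: float
    ramp: bool = False


class BathBlock(_Strict):
    t0_c: float = 25.0
    hext_w_m2k: float = 1000.0
    segments: list[SegmentBlock]

    def build(self) -> BathProgram:
        return BathProgram(
            self.t0_c,
            tuple(BathSegment(s.duration_s, s.temperature_c, s.ramp) for s in self.segments),
            self.hext_w_m2k,
        )


class RateBlock(_Strict):
    """Flat serialization of an Arrhenius rate: k_ref at T_ref, Ea in kJ/mol."""

    k_ref_per_s: float
    t_ref_c: float
    ea_kj_per_mol: float

    def build(self) -> ArrheniusRate:
        return ArrheniusRate(
            self.k_ref_per_s, self.t_ref_c + CELSIUS_OFFSET, self.ea_kj_per_mol * 1e3
        )

    @classmethod
    def from_rate(cls, rate: ArrheniusRate) -> "RateBlock":
        return cls(
            k_ref_per_s=rate.k_ref,
            t_ref_c=rate.t_ref - CELSIUS_OFFSET,
            ea_kj_per_mol=rate.activation_energy / 1e3,
        )


class MonophasicBlock(_Strict):
    rate: RateBlock

    def build(self) -> MonophasicInactivation:
        return MonophasicInactivation(self.rate.build())


class BiphasicBlock(_Strict):
    fraction_labile: float | None = None
    isoform_ratio: float | None = None
    rate_labile: RateBlock
    rate_stable: RateBlock

    def build(self) -> BiphasicInactivation:
        if (self.fraction_labile is None) == (self.isoform_ratio is None):
            raise ConfigError(
                "give exactly one of fraction_labile / isoform_ratio"
            )
        if self.isoform_ratio is not None:
            return BiphasicInactivation.from_ratio(
                self.isoform_ratio, self.rate_labile.build(), self.rate_stable.build()
            )
        return BiphasicInactivation(
            self.fraction_labile, self.rate_labile.build(), self.rate_stable.build()
        )


class PectinBlock(_Strict):
    k_beta: RateBlock
    k_m: RateBlock
    k_d: RateBlock
    dm0: float = 0.8

    def build(self) -> PectinParameters:
        return PectinParameters(
            self.k_beta.build(), self.k_m.build(), self.k_d.build(), self.dm0
        )


class ModelsBlock(_Strict):
    monophasic: dict[str, MonophasicBlock] = Field(default_factory=dict)
    biphasic: dict[str, BiphasicBlock] = Field(default_factory=dict)
    pectin: PectinBlock | None = None

    def build_enzymes(self) -> dict:
        out: dict = {name: m.build() for name, m in self.monophasic.items()}
        out.update({name: m.build() for name, m in self.biphasic.items()})
        return out


class SolverBlock(_Strict):
    dt_s: float | None = None
    t_end_s: float | None = None


class TTIBlock(_Strict):
    ea_kj_per_mol: float = 110.0
    t_ref_c: float = 90.0
    k_ref_per_s: float | None = None


class FreeParamBlock(_Strict):
    initial: float
    lower: float
    upper: float
    log_scale: bool = False


class FitBlock(_Strict):
    model: str  # isothermal_monophasic | isothermal_biphasic | coupled_monophasic | coupled_biphasic
    observable: str
    t_ref_c: float = 80.0
    free: dict[str, FreeParamBlock]
    fixed: dict[str, float] = Field(default_factory=dict)
    loss: str = "weighted_l2"
    method: str = "bounded_quasi_newton"
    tolerance: float = 1e-4
    multistart: int = 1


class GenerateBlock(_Strict):
    kind: str = "isothermal"  # isothermal | blanching
    temperatures_c: list[float] = Field(default_factory=lambda: [70.0, 80.0, 90.0])
    times_s: list[float] = Field(default_factory=lambda: [60.0, 120.0, 300.0, 600.0])
    enzyme: str = "pod"
    sigma: float = 0.0
    texture: bool = False


class RunConfig(_Strict):
    """Top-level configuration with all defaults resolved."""

    geometry: GeometryBlock = Field(default_factory=GeometryBlock)
    composition: CompositionBlock = Field(default_factory=CompositionBlock)
    bath: BathBlock | None = None
    models: ModelsBlock = Field(default_factory=ModelsBlock)
    solver: SolverBlock = Field(default_factory=SolverBlock)
    tti: TTIBlock = Field(default_factory=TTIBlock)
    fit: FitBlock | None = None
    generate: GenerateBlock = Field(default_factory=GenerateBlock)
    seed: int = 0
    log_level: str = "info"


def _friendly(err: PydanticError) -> ConfigError:
    parts = []
    for e in err.errors():
        loc = ".".join(str(x) for x in e["loc"]) or "<root>"
        parts.append(f"{loc}: {e['msg']}")
    return ConfigError("invalid configuration — " + "; ".join(parts))


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON config; defaults are resolved."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    try:
        return RunConfig.model_validate(raw)
    except PydanticError as err:
        raise _friendly(err) from None


def dump_config(cfg: RunConfig) -> str:
    """Serialize the resolved config back to YAML (round-trip stable)."""
    return yaml.safe_dump(cfg.model_dump(), sort_keys=True)
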