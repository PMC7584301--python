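"""Run configuration: schema-validated YAML in, fully resolved defaults out.

Unknown keys are rejected; every field is validated before any
computation; the resolved configuration is echoed to the log so a run's
provenance is always recorded.
"""
from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .constitutive import Material, elastic_constants
from .geometry import DomainSpec
from .quantify import default_edges
from .solver import ContactSpec, LoadCase, SolverSettings

__all__ = ["ConfigError", "RunConfig", "load_config", "save_config"]


class ConfigError(ValueError):
    pass


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DomainConfig(_Model):
    tissue_width: float = 200.0
    tissue_height: float = 75.0
    tissue_depth: float = 250.0
    effective_depth: float = 90.0
    dressing_thickness: float = 5.5
    dressing_perimeter_extent: float = 100.0
    mattress_thickness: float = 75.0
    prominence_tip_radius: float = 10.0
    prominence_depth_below_skin: float = 15.0
    dimensionality: str = "2D-plane-strain"

    def to_spec(self) -> DomainSpec:
        spec = DomainSpec(**self.model_dump())
        spec.validate()
        return spec


class MaterialConfig(_Model):
    family: str = "neo_hookean"
    E: float | None = None
    nu: float | None = None
    G: float | None = None
    K: float | None = None
    lam: float | None = None
    solid_fraction: float = Field(default=1.0, gt=0.0, le=1.0)

    @field_validator("family")
    @classmethod
    def _family(cls, v):
        if v not in ("neo_hookean", "linear_elastic"):
            raise ValueError("family must be neo_hookean or linear_elastic")
        return v

    @model_validator(mode="after")
    def _two_constants(self):
        given = {
            k: getattr(self, k)
            for k in ("E", "nu", "G", "K", "lam")
            if getattr(self, k) is not None
        }
        if len(given) != 2:
            raise ValueError("exactly two elastic constants required")
        try:
            elastic_constants(**given)  # range check, incl. nu < 0.5
        except Exception as exc:
            raise ValueError(str(exc)) from exc
        return self

    def to_material(self, name: str = "") -> Material:
        given = {
            k: getattr(self, k)
            for k in ("E", "nu", "G", "K", "lam")
            if getattr(self, k) is not None
        }
        return Material(
            family=self.family,
            constants=elastic_constants(**given),
            solid_fraction=self.solid_fraction,
            name=name,
        )


class LoadConfig(_Model):
    direction_angle: float = Field(default=45.0, ge=0.0, lt=90.0)
    target_reaction_force: float = Field(default=40.0, gt=0.0)
    max_displacement_guess: float = Field(default=30.0, gt=0.0)

    def to_load(self) -> LoadCase:
        return LoadCase(**self.model_dump())


class ContactConfig(_Model):
    friction_coefficient: float = Field(default=0.4, ge=0.0)
    skin_friction_coefficient: float = Field(default=0.7, ge=0.0)
    normal_penalty: float | None = Field(default=None, gt=0.0)
    tangential_penalty: float | None = Field(default=None, gt=0.0)

    def to_contact(self) -> ContactSpec:
        return ContactSpec(
            **self.model_dump(exclude={"skin_friction_coefficient"})
        )


class SolverConfig(_Model):
    load_steps: int = Field(default=10, ge=1)
    newton_tolerance: float = Field(default=1e-6, gt=0.0)
    max_newton_iterations: int = Field(default=60, ge=1)
    force_target_tolerance: float = Field(default=0.1, gt=0.0)
    line_search_enabled: bool = True

    def to_settings(self) -> SolverSettings:
        return SolverSettings(**self.model_dump())


class HistogramConfig(_Model):
    lo: float = Field(default=0.05, ge=0.0)
    hi: float = 1.0
    n_bins: int = Field(default=19, ge=1)

    @model_validator(mode="after")
    def _range(self):
        if self.hi <= self.lo:
            raise ValueError("hi must exceed lo")
        return self

    def edges(self):
        return default_edges(self.lo, self.hi, self.n_bins)


class PathsConfig(_Model):
    mesh: str | None = None
    curves: str | None = None
    output_dir: str = "."


class RunConfig(_Model):
    domain: DomainConfig = DomainConfig()
    materials: dict[str, MaterialConfig] = {}
    load: LoadConfig = LoadConfig()
    contact: ContactConfig = ContactConfig()
    solver: SolverConfig = SolverConfig()
    histogram: HistogramConfig = HistogramConfig()
    paths: PathsConfig = PathsConfig()
    resolution: float = Field(default=0.15, gt=0.0)
    foam_poisson: float = Field(default=0.1, gt=-1.0, lt=0.5)
    seed: int = 0
    verbosity: int = Field(default=1, ge=0, le=3)

    @field_validator("materials")
    @classmethod
    def _regions(cls, v):
        allowed = {"tissue", "bone", "mattress", "dressing"}
        bad = set(v) - allowed
        if bad:
            raise ValueError(f"unknown material region(s) {sorted(bad)}")
        return v

    def resolved_materials(self) -> dict:
        from .constitutive import BONE, MATTRESS, TISSUE

        mats = {"tissue": TISSUE, "bone": BONE, "mattress": MATTRESS}
        for region, mc in self.materials.items():
            mats[region] = mc.to_material(name=region)
        return mats


def load_config(path) -> RunConfig:
    """Read and validate a YAML run configuration.

    Raises :class:`ConfigError` naming the offending key on schema
    violations; missing files surface as ``FileNotFoundError``.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("top-level config must be a mapping")
    try:
        return RunConfig.model_validate(data)
    except Exception as exc:
        raise ConfigError(str(exc)) from exc


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))
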