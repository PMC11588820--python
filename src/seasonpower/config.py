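"""Run configuration: the app-facing parameter names, validation, YAML I/O.

Config keys are the kebab-cased display names of the original interface, so
the published parameter primer doubles as documentation for the config file
and the CLI flags.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import yaml

from .correlation import SeasonalModel
from .sample_size import StudySpec
from .seasonal_sim import SeasonalCurveSpec

__all__ = ["RunConfig", "CONFIG_KEYS", "DEFAULTS"]

# attribute name -> config/flag key
_KEYMAP = {
    "k": "k",
    "n_initial": "n",
    "rho": "rho",
    "theta": "theta",
    "seasonality_noise": "seasonality-noise",
    "between_site_clustering": "between-site-clustering",
    "power": "power",
    "effect_size": "effect-size",
    "alpha": "alpha",
    "n_species": "number-of-mosquito-species",
    "m_1": "number-of-mosquitoes-for-species-1",
    "m_2": "number-of-mosquitoes-for-species-2",
    "sd_1": "standard-deviation-for-effect-mosquito-species-1",
    "sd_2": "standard-deviation-for-effect-mosquito-species-2",
    "random_seed": "random-seed",
}
_INV_KEYMAP = {v: k for k, v in _KEYMAP.items()}
CONFIG_KEYS = tuple(_KEYMAP.values())

#: Illustrative defaults (mirroring the reference screenshots); a banner
#: warns that they must not be used for real survey planning.
DEFAULTS = {
    "k": 10,
    "n": 2,
    "rho": 0.2,
    "theta": 0.1,
    "seasonality-noise": 2.0,
    "between-site-clustering": 0.2,
    "power": 0.8,
    "effect-size": 20.0,
    "alpha": 0.05,
    "number-of-mosquito-species": 1,
    "number-of-mosquitoes-for-species-1": 15,
    "number-of-mosquitoes-for-species-2": None,
    "standard-deviation-for-effect-mosquito-species-1": 3.0,
    "standard-deviation-for-effect-mosquito-species-2": None,
    "random-seed": 2,
}


@dataclass(frozen=True)
class RunConfig:
    k: int
    n_initial: float
    rho: float
    theta: float
    seasonality_noise: float
    between_site_clustering: float
    power: float
    effect_size: float
    alpha: float
    n_species: int
    m_1: int
    sd_1: float
    random_seed: int
    m_2: int | None = None
    sd_2: float | None = None

    # -- domain-object views (validation happens in the owning types) ----

    def study_spec(self) -> StudySpec:
        return StudySpec(
            x=self.effect_size,
            sd_effect_1=self.sd_1,
            m_1=self.m_1,
            rho_c=self.between_site_clustering,
            alpha=self.alpha,
            power=self.power,
            n_species=self.n_species,
            sd_effect_2=self.sd_2,
            m_2=self.m_2,
        )

    def seasonal_model(self) -> SeasonalModel:
        return SeasonalModel(rho=self.rho, theta=self.theta)

    def curve_spec(self) -> SeasonalCurveSpec:
        return SeasonalCurveSpec(
            k_max=self.k,
            n_initial=self.n_initial,
            noise=self.seasonality_noise,
            seed=self.random_seed,
        )

    def validate(self) -> None:
        """Run every owning type's validation."""
        self.study_spec()
        self.seasonal_model()
        self.curve_spec()

    # -- (de)serialisation ----------------------------------------------

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        unknown = sorted(set(mapping) - set(CONFIG_KEYS))
        if unknown:
            raise KeyError(
                f"unknown config keys {unknown}; accepted keys are "
                f"{sorted(CONFIG_KEYS)}")
        merged = dict(DEFAULTS)
        merged.update(mapping)
        kwargs = {_INV_KEYMAP[key]: value for key, value in merged.items()}
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def to_mapping(self) -> dict:
        return {_KEYMAP[f.name]: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        return cls.from_mapping(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_mapping(), fh, sort_keys=True)
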