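"""Configuration objects for the synthetic cohort generator and factor model.

The generator is parameterized by a :class:`GeneratorConfig`: a covariate
taxonomy (early-life, current socioeconomic, demographic, lifestyle), planted
regression effects on the latent overall capacity and its five subdomains,
a mediation path from early-life levels to a latent current-SES propensity,
a continuous wealth model, a second-order factor measurement structure, and
optional missingness / selection models.  The shipped default configuration
(``lifecap/data/default_config.yaml``) encodes an ageing-survey scenario with
11 early-life factor groups and 4 current socioeconomic factors.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Mapping, Sequence

import yaml

CATEGORIES = ("early_life", "current_ses", "demographic", "lifestyle")
SUBDOMAINS = ("locomotion", "cognitive", "vitality", "sensory", "psychological")
OUTCOMES = ("overall",) + SUBDOMAINS


class ConfigurationError(ValueError):
    """Raised when a generator or pipeline configuration is malformed."""


@dataclass
class CovariateSpec:
    """One categorical covariate of the cohort.

    Parameters
    ----------
    name : str
        Column name in the cohort table.
    category : str
        One of ``early_life``, ``current_ses``, ``demographic``, ``lifestyle``.
    group : str
        Factor group the covariate belongs to (several covariates may measure
        one conceptual factor, e.g. maternal and paternal literacy both belong
        to ``parental_education``).
    levels : sequence of str
        Ordered category labels, least to most advantaged.
    reference : str
        Reference level omitted from dummy coding.
    marginal : sequence of float
        Marginal probability of each level; sums to 1.
    advantage_loading : float
        Strength of dependence on the latent childhood-advantage variable.
    effects : mapping
        ``level -> {outcome -> additive effect}`` on the latent capacity
        variables, for non-reference levels.
    """

    name: str
    category: str
    group: str
    levels: tuple[str, ...]
    reference: str
    marginal: tuple[float, ...]
    advantage_loading: float = 0.0
    effects: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.levels = tuple(str(x) for x in self.levels)
        self.marginal = tuple(float(p) for p in self.marginal)
        if self.category not in CATEGORIES:
            raise ConfigurationError(
                f"covariate {self.name!r}: unknown category {self.category!r}"
            )
        if len(self.levels) < 2:
            raise ConfigurationError(f"covariate {self.name!r}: needs >= 2 levels")
        if len(self.marginal) != len(self.levels):
            raise ConfigurationError(
                f"covariate {self.name!r}: marginal length != number of levels"
            )
        if any(p < 0 for p in self.marginal):
            raise ConfigurationError(f"covariate {self.name!r}: negative marginal")
        if abs(sum(self.marginal) - 1.0) > 1e-8:
            raise ConfigurationError(
                f"covariate {self.name!r}: marginal sums to {sum(self.marginal)}"
            )
        if self.reference not in self.levels:
            raise ConfigurationError(
                f"covariate {self.name!r}: reference {self.reference!r} not a level"
            )
        for lvl, eff in self.effects.items():
            if lvl not in self.levels:
                raise ConfigurationError(
                    f"covariate {self.name!r}: effect for unknown level {lvl!r}"
                )
            if lvl == self.reference:
                raise ConfigurationError(
                    f"covariate {self.name!r}: effect planted on reference level"
                )
            unknown = set(eff) - set(OUTCOMES)
            if unknown:
                raise ConfigurationError(
                    f"covariate {self.name!r}: unknown outcomes {sorted(unknown)}"
                )

    @property
    def nonreference_levels(self) -> tuple[str, ...]:
        return tuple(l for l in self.levels if l != self.reference)

    def effect(self, level: str, outcome: str) -> float:
        return float(self.effects.get(level, {}).get(outcome, 0.0))


@dataclass
class FactorStructure:
    """Second-order measurement structure for the capacity indicators.

    ``indicator_map`` assigns every indicator to exactly one of the five
    subdomains.  ``loadings``/``second_order_loadings``/``disturbances``/
    ``uniquenesses`` are the data-generating (and starting) values; the first
    indicator of each subdomain is treated as the marker with loading fixed
    at 1, and the first subdomain is the marker of the overall factor.
    """

    subdomains: tuple[str, ...]
    indicator_map: dict[str, tuple[str, ...]]
    loadings: dict[str, float]
    second_order_loadings: dict[str, float]
    disturbances: dict[str, float]
    uniquenesses: dict[str, float]

    def __post_init__(self) -> None:
        self.subdomains = tuple(self.subdomains)
        if len(self.subdomains) != 5:
            raise ConfigurationError("exactly five subdomains are required")
        self.indicator_map = {d: tuple(v) for d, v in self.indicator_map.items()}
        if set(self.indicator_map) != set(self.subdomains):
            raise ConfigurationError("indicator_map keys must equal subdomains")
        seen: set[str] = set()
        for d, inds in self.indicator_map.items():
            if not inds:
                raise ConfigurationError(f"subdomain {d!r} has no indicators")
            dup = seen & set(inds)
            if dup:
                raise ConfigurationError(
                    f"indicators {sorted(dup)} assigned to more than one subdomain"
                )
            seen |= set(inds)
        for ind in self.indicators:
            if ind not in self.loadings:
                raise ConfigurationError(f"no loading for indicator {ind!r}")
            if ind not in self.uniquenesses:
                raise ConfigurationError(f"no uniqueness for indicator {ind!r}")
        for d in self.subdomains:
            if d not in self.second_order_loadings:
                raise ConfigurationError(f"no second-order loading for {d!r}")
            if d not in self.disturbances:
                raise ConfigurationError(f"no disturbance variance for {d!r}")

    @property
    def indicators(self) -> tuple[str, ...]:
        return tuple(i for d in self.subdomains for i in self.indicator_map[d])

    def subdomain_of(self, indicator: str) -> str:
        for d, inds in self.indicator_map.items():
            if indicator in inds:
                return d
        raise KeyError(indicator)

    def marker(self, subdomain: str) -> str:
        """First indicator of a subdomain; its loading is fixed at 1."""
        return self.indicator_map[subdomain][0]

    def to_dict(self) -> dict[str, Any]:
        return {
            "subdomains": list(self.subdomains),
            "indicator_map": {d: list(v) for d, v in self.indicator_map.items()},
            "loadings": dict(self.loadings),
            "second_order_loadings": dict(self.second_order_loadings),
            "disturbances": dict(self.disturbances),
            "uniquenesses": dict(self.uniquenesses),
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "FactorStructure":
        return cls(
            subdomains=tuple(d["subdomains"]),
            indicator_map={k: tuple(v) for k, v in d["indicator_map"].items()},
            loadings={k: float(v) for k, v in d["loadings"].items()},
            second_order_loadings={
                k: float(v) for k, v in d["second_order_loadings"].items()
            },
            disturbances={k: float(v) for k, v in d["disturbances"].items()},
            uniquenesses={k: float(v) for k, v in d["uniquenesses"].items()},
        )


@dataclass
class WealthModel:
    advantage_loading: float = 0.5
    mediation_loading: float = 1.0
    noise_sd: float = 1.0
    log_mean: float = 9.0
    log_scale: float = 0.8

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigurationError("wealth noise_sd must be >= 0")


@dataclass
class GeneratorConfig:
    """Full parameterization of the synthetic cohort generator."""

    n: int
    seed: int
    covariates: list[CovariateSpec]
    mediation_coefs: dict[str, dict[str, float]] = field(default_factory=dict)
    wealth_model: WealthModel = field(default_factory=WealthModel)
    factor_structure: FactorStructure | None = None
    selection_model: dict[str, float] = field(default_factory=dict)
    missing_rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ConfigurationError(f"n must be >= 0, got {self.n}")
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate covariate names")
        for cov, coefs in self.mediation_coefs.items():
            spec = self.covariate(cov)
            if spec is None:
                raise ConfigurationError(f"mediation on unknown covariate {cov!r}")
            if spec.category != "early_life":
                raise ConfigurationError(
                    f"mediation coefficient on non-early-life covariate {cov!r}"
                )
            unknown = set(coefs) - set(spec.levels)
            if unknown:
                raise ConfigurationError(
                    f"mediation on unknown levels {sorted(unknown)} of {cov!r}"
                )
        for col, rate in self.missing_rates.items():
            if not 0.0 <= float(rate) <= 1.0:
                raise ConfigurationError(f"missing rate for {col!r} outside [0, 1]")

    def covariate(self, name: str) -> CovariateSpec | None:
        for c in self.covariates:
            if c.name == name:
                return c
        return None

    def by_category(self, category: str) -> list[CovariateSpec]:
        return [c for c in self.covariates if c.category == category]

    @property
    def early_life_groups(self) -> tuple[str, ...]:
        seen: list[str] = []
        for c in self.by_category("early_life"):
            if c.group not in seen:
                seen.append(c.group)
        return tuple(seen)

    def replace(self, **kwargs: Any) -> "GeneratorConfig":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        return {
            "n": self.n,
            "seed": self.seed,
            "covariates": [
                {
                    "name": c.name,
                    "category": c.category,
                    "group": c.group,
                    "levels": list(c.levels),
                    "reference": c.reference,
                    "marginal": list(c.marginal),
                    "advantage_loading": c.advantage_loading,
                    "effects": {l: dict(e) for l, e in c.effects.items()},
                }
                for c in self.covariates
            ],
            "mediation_coefs": {
                k: dict(v) for k, v in self.mediation_coefs.items()
            },
            "wealth_model": dataclasses.asdict(self.wealth_model),
            "factor_structure": (
                self.factor_structure.to_dict() if self.factor_structure else None
            ),
            "selection_model": dict(self.selection_model),
            "missing_rates": dict(self.missing_rates),
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "GeneratorConfig":
        try:
            covs = [
                CovariateSpec(
                    name=c["name"],
                    category=c["category"],
                    group=c.get("group", c["name"]),
                    levels=tuple(str(x) for x in c["levels"]),
                    reference=str(c["reference"]),
                    marginal=tuple(c["marginal"]),
                    advantage_loading=float(c.get("advantage_loading", 0.0)),
                    effects={
                        str(l): {k: float(v) for k, v in e.items()}
                        for l, e in (c.get("effects") or {}).items()
                    },
                )
                for c in d["covariates"]
            ]
        except KeyError as exc:
            raise ConfigurationError(f"covariate spec missing field {exc}") from exc
        fs = d.get("factor_structure")
        return cls(
            n=int(d["n"]),
            seed=int(d.get("seed", 0)),
            covariates=covs,
            mediation_coefs={
                str(k): {str(l): float(v) for l, v in m.items()}
                for k, m in (d.get("mediation_coefs") or {}).items()
            },
            wealth_model=WealthModel(**(d.get("wealth_model") or {})),
            factor_structure=FactorStructure.from_dict(fs) if fs else None,
            selection_model={
                str(k): float(v) for k, v in (d.get("selection_model") or {}).items()
            },
            missing_rates={
                str(k): float(v) for k, v in (d.get("missing_rates") or {}).items()
            },
        )


def load_config(path: str) -> GeneratorConfig:
    """Load a generator configuration from a YAML (or JSON) file."""
    with open(path) as fh:
        return GeneratorConfig.from_dict(yaml.safe_load(fh))


def default_config(n: int | None = None, seed: int | None = None) -> GeneratorConfig:
    """The shipped default configuration (CHARLS-like study conditions)."""
    text = resources.files("lifecap.data").joinpath("default_config.yaml").read_text()
    cfg = GeneratorConfig.from_dict(yaml.safe_load(text))
    if n is not None:
        cfg = cfg.replace(n=int(n))
    if seed is not None:
        cfg = cfg.replace(seed=int(seed))
    return cfg
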