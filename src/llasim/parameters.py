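"""Biological and population-genetic model constants, validation and config I/O.

Two parameter blocks drive everything else in the package:

``BiologyParams``
    Vector biology of an adult female *Anopheles* mosquito — background
    mortality hazard, gonotrophic-cycle timing, host-choice probabilities,
    attack mortalities, fecundity and the sporogonic development time of
    *Plasmodium* inside the mosquito.  Defaults are the baseline values used
    throughout the analyses.

``PopulationParams``
    Single-locus resistance genetics — initial genotype composition,
    dominance of the resistance allele, the lag (in gonotrophic-cycle
    periods) between egg laying and adult emergence, and male fitness
    factors.

Configuration files are YAML (JSON is a YAML subset and also accepted) with
optional sections ``biology``, ``population`` and ``interventions``; any key
left out falls back to the baseline default, and unknown keys are an error.
A bundled ``data/baseline.yaml`` spells out every default explicitly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "BiologyParams",
    "PopulationParams",
    "ConfigError",
    "ValidationError",
    "load_config",
    "save_config",
    "baseline_config_path",
]


class ConfigError(ValueError):
    """A configuration file is malformed or contains unknown keys."""


class ValidationError(ValueError):
    """A parameter value violates its documented bounds."""


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"{name} must be in [0, 1], got {value!r}")


def _check_nonneg(name: str, value: float) -> None:
    if value < 0:
        raise ValidationError(f"{name} must be >= 0, got {value!r}")


@dataclass(frozen=True)
class BiologyParams:
    """Baseline vector-biology constants.

    Attributes
    ----------
    background_mortality_rate
        Instantaneous background mortality hazard, per day.  Survival over
        ``t`` days of activity is ``exp(-rate * t)``.
    cycle_length
        Length of one gonotrophic cycle (blood feed, rest, oviposit), days.
    host_search_time, resting_time, oviposition_search_time
        Durations of the three activity segments within a cycle, days.
        Background (and fungal) mortality is applied over these segments
        only; the small residual slack in the cycle length carries no
        hazard.
    infectious_human_fraction
        Proportion of the human population infectious for malaria.
    nonhuman_host_prob
        Probability that a host-seeking mosquito attacks a non-human host.
    pre_bite_attack_mortality, post_bite_attack_mortality
        Probability of being killed by host defences before / after biting
        (insecticide mortality excluded).
    malaria_infection_prob
        Probability a mosquito acquires malaria when biting an infectious
        human.
    eggs_per_laying
        Eggs laid per successful oviposition.
    sporogony_cycles
        Sporogonic development time expressed in whole gonotrophic cycles
        (``D``); derived from ``sporogony_days``.
    sporogony_days
        Sporogonic development time in days; documentation only — the model
        works in whole cycles.
    max_age_classes
        Number of feeding cycles tracked before the cohort is truncated.
    infectious_at_m_equal_d
        Infectiousness boundary switch.  A bite is infectious when the
        malaria infection is *strictly older* than ``sporogony_cycles``
        (default, ``False``: age ``m > D``, i.e. the elapsed time covers the
        full sporogony in days), or already at ``m == D`` when ``True``.
    """

    background_mortality_rate: float = 0.1175
    cycle_length: float = 2.85
    host_search_time: float = 1.26
    oviposition_search_time: float = 1.26
    resting_time: float = 0.32
    infectious_human_fraction: float = 0.0428
    nonhuman_host_prob: float = 0.17
    pre_bite_attack_mortality: float = 0.05
    post_bite_attack_mortality: float = 0.05
    malaria_infection_prob: float = 1.0
    eggs_per_laying: float = 100.0
    sporogony_cycles: int = 3
    sporogony_days: float = 10.78
    max_age_classes: int = 10
    infectious_at_m_equal_d: bool = False

    def __post_init__(self) -> None:
        for name in (
            "infectious_human_fraction",
            "nonhuman_host_prob",
            "pre_bite_attack_mortality",
            "post_bite_attack_mortality",
            "malaria_infection_prob",
        ):
            _check_prob(name, getattr(self, name))
        for name in (
            "background_mortality_rate",
            "cycle_length",
            "host_search_time",
            "oviposition_search_time",
            "resting_time",
            "eggs_per_laying",
            "sporogony_days",
        ):
            _check_nonneg(name, getattr(self, name))
        segments = (
            self.host_search_time + self.resting_time + self.oviposition_search_time
        )
        if segments > self.cycle_length + 1e-9:
            raise ValidationError(
                "host_search_time + resting_time + oviposition_search_time "
                f"({segments:g}) must not exceed cycle_length ({self.cycle_length:g})"
            )
        if self.sporogony_cycles < 1:
            raise ValidationError(
                f"sporogony_cycles must be >= 1, got {self.sporogony_cycles!r}"
            )
        if self.max_age_classes <= self.sporogony_cycles:
            raise ValidationError(
                "max_age_classes must exceed sporogony_cycles "
                f"({self.max_age_classes!r} <= {self.sporogony_cycles!r})"
            )

    @property
    def infectious_age_threshold(self) -> int:
        """Minimum malaria age (in cycles) at which a bite is infectious."""
        if self.infectious_at_m_equal_d:
            return self.sporogony_cycles
        return self.sporogony_cycles + 1


@dataclass(frozen=True)
class PopulationParams:
    """Resistance-genetics and population-dynamics constants.

    ``initial_genotype_fractions`` is the (ss, sr, rr) composition at the
    start of the run; the baseline seeds heterozygotes at 1e-9.  ``dominance``
    is 1 when heterozygotes express the resistant phenotype, 0 when they are
    phenotypically susceptible.  ``recruitment_lag`` is the number of periods
    between egg laying and adult emergence.
    """

    initial_genotype_fractions: tuple[float, float, float] = (
        1.0 - 1e-9,
        1e-9,
        0.0,
    )
    dominance: int = 1
    recruitment_lag: int = 3
    male_fitness_factors: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_periods: int = 2000

    def __post_init__(self) -> None:
        fractions = tuple(float(x) for x in self.initial_genotype_fractions)
        object.__setattr__(self, "initial_genotype_fractions", fractions)
        if len(fractions) != 3:
            raise ValidationError(
                "initial_genotype_fractions must have exactly three entries (ss, sr, rr)"
            )
        for g, x in zip(("ss", "sr", "rr"), fractions):
            _check_prob(f"initial_genotype_fractions[{g}]", x)
        if abs(sum(fractions) - 1.0) > 1e-9:
            raise ValidationError(
                f"initial_genotype_fractions must sum to 1, got {sum(fractions)!r}"
            )
        if self.dominance not in (0, 1):
            raise ValidationError(f"dominance must be 0 or 1, got {self.dominance!r}")
        if self.recruitment_lag < 0:
            raise ValidationError(
                f"recruitment_lag must be >= 0, got {self.recruitment_lag!r}"
            )
        factors = tuple(float(x) for x in self.male_fitness_factors)
        object.__setattr__(self, "male_fitness_factors", factors)
        if len(factors) != 3 or any(x <= 0 for x in factors):
            raise ValidationError(
                f"male_fitness_factors must be three positive numbers, got {factors!r}"
            )
        if self.n_periods < 1:
            raise ValidationError(f"n_periods must be >= 1, got {self.n_periods!r}")


# --------------------------------------------------------------------------
# Config I/O


def _build_from_section(cls: type, section: dict[str, Any], name: str) -> Any:
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ConfigError(
            f"unknown key(s) in '{name}' section: {', '.join(sorted(unknown))}"
        )
    kwargs: dict[str, Any] = {}
    for key, value in section.items():
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path):
    """Read a YAML/JSON config into validated parameter objects.

    Returns ``(BiologyParams, PopulationParams, list[Intervention])``.  An
    empty file (or any omitted section) yields the full baseline defaults
    and an empty intervention list.
    """
    from .interventions import Intervention  # local import to avoid a cycle

    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"top level of {path} must be a mapping")
    unknown = set(raw) - {"biology", "population", "interventions"}
    if unknown:
        raise ConfigError(f"unknown top-level section(s): {', '.join(sorted(unknown))}")

    bio = _build_from_section(BiologyParams, raw.get("biology") or {}, "biology")
    pop = _build_from_section(
        PopulationParams, raw.get("population") or {}, "population"
    )
    iv_specs = raw.get("interventions") or []
    if not isinstance(iv_specs, list):
        raise ConfigError("'interventions' must be a list of mappings")
    interventions = [Intervention.from_dict(spec) for spec in iv_specs]
    return bio, pop, interventions


def save_config(
    path: str | Path,
    bio: BiologyParams,
    pop: PopulationParams,
    interventions=(),
) -> None:
    """Write parameters back to YAML such that :func:`load_config` round-trips."""
    doc = {
        "biology": dataclasses.asdict(bio),
        "population": {
            "initial_genotype_fractions": list(pop.initial_genotype_fractions),
            "dominance": pop.dominance,
            "recruitment_lag": pop.recruitment_lag,
            "male_fitness_factors": list(pop.male_fitness_factors),
            "n_periods": pop.n_periods,
        },
        "interventions": [iv.to_dict() for iv in interventions],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def baseline_config_path() -> Path:
    """Path to the bundled baseline configuration file."""
    return Path(resources.files("llasim").joinpath("data/baseline.yaml"))
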