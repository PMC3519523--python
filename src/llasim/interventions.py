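"""Vector-control treatments and their per-event probabilities and hazards.

Two product classes are represented:

* **instant-kill chemical insecticides** (e.g. pyrethroid IRS) — a mosquito
  resting indoors after a human blood meal is killed outright with the
  composite coverage probability, possibly reduced by contact repellency
  (excito-repellency drives some mosquitoes off the treated surface before
  they pick up a lethal dose);
* **delayed-action fungal biopesticides** — the same resting contact instead
  *infects* the mosquito; the infection is harmless until an ``initiation_day``
  after exposure and thereafter imposes a fixed daily mortality rate.
  Virulence may differ between malaria-infected and malaria-free mosquitoes.

The two-parameter virulence schedule (initiation day, daily mortality rate)
is converted to a constant hazard ``h = -ln(1 - daily_mortality)`` so that a
mosquito alive at the start of a post-initiation day survives it with
probability ``1 - daily_mortality``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any

from .parameters import ValidationError

__all__ = [
    "VirulenceSchedule",
    "Intervention",
    "effective_contact_prob",
    "fungal_survival",
]

KINDS = ("none", "instant_kill", "biopesticide")


@dataclass(frozen=True)
class VirulenceSchedule:
    """Fungus-induced incremental mortality: nothing before ``initiation_day``
    (days post-infection), then a fixed ``daily_mortality`` probability."""

    initiation_day: float = 0.0
    daily_mortality: float = 0.0

    def __post_init__(self) -> None:
        if self.initiation_day < 0:
            raise ValidationError(
                f"initiation_day must be >= 0, got {self.initiation_day!r}"
            )
        if not 0.0 <= self.daily_mortality <= 1.0:
            raise ValidationError(
                f"daily_mortality must be in [0, 1], got {self.daily_mortality!r}"
            )

    @property
    def hazard(self) -> float:
        """Constant post-initiation hazard per day; ``inf`` at 100% daily
        mortality."""
        if self.daily_mortality >= 1.0:
            return math.inf
        return -math.log1p(-self.daily_mortality)


def fungal_survival(t0: float, t1: float, sched: VirulenceSchedule) -> float:
    """Probability a fungus-infected mosquito survives the fungal hazard over
    the interval ``[t0, t1]`` of days since infection.

    Only the part of the interval past the initiation day carries hazard.
    The factor multiplies (never replaces) background survival.  Negative
    times (before infection) are clipped to zero hazard.
    """
    if t1 < t0:
        raise ValueError(f"interval end {t1!r} precedes start {t0!r}")
    overlap = max(0.0, t1 - max(t0, sched.initiation_day, 0.0))
    if overlap <= 0.0:
        return 1.0
    if sched.daily_mortality >= 1.0:
        return 0.0
    return math.exp(-sched.hazard * overlap)


@dataclass(frozen=True)
class Intervention:
    """A vector-control treatment applied to surfaces contacted while resting
    after a human blood meal.

    ``coverage`` is the composite probability of being in a treated property,
    contacting the product and being affected by it; ``repellency`` is the
    fraction of contacts driven off before acquiring an effective dose
    (meaningful for instant-kill chemicals only — fungal spores show no
    contact irritancy, so it is forced to zero for biopesticides).
    """

    kind: str = "none"
    coverage: float = 0.0
    repellency: float = 0.0
    virulence_infected: VirulenceSchedule | None = None
    virulence_uninfected: VirulenceSchedule | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValidationError(
                f"kind must be one of {KINDS}, got {self.kind!r}"
            )
        for name in ("coverage", "repellency"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {value!r}")
        if self.kind == "none" and self.coverage != 0.0:
            object.__setattr__(self, "coverage", 0.0)
        if self.kind == "biopesticide":
            if self.repellency != 0.0:
                object.__setattr__(self, "repellency", 0.0)
            if self.virulence_infected is None:
                object.__setattr__(self, "virulence_infected", VirulenceSchedule())
            if self.virulence_uninfected is None:
                object.__setattr__(
                    self, "virulence_uninfected", self.virulence_infected
                )

    # -- constructors -------------------------------------------------------

    @classmethod
    def none(cls) -> "Intervention":
        return cls(kind="none")

    @classmethod
    def instant_kill(cls, coverage: float, repellency: float = 0.0) -> "Intervention":
        return cls(kind="instant_kill", coverage=coverage, repellency=repellency)

    @classmethod
    def biopesticide(
        cls,
        coverage: float,
        initiation_day: float,
        daily_mortality: float,
        uninfected_initiation_day: float | None = None,
        uninfected_daily_mortality: float | None = None,
    ) -> "Intervention":
        """Biopesticide with a shared or malaria-differential virulence
        schedule.  If either ``uninfected_*`` argument is given, malaria-free
        mosquitoes follow their own schedule (missing pieces default to the
        infected schedule's)."""
        infected = VirulenceSchedule(initiation_day, daily_mortality)
        uninfected = infected
        if uninfected_initiation_day is not None or uninfected_daily_mortality is not None:
            uninfected = VirulenceSchedule(
                initiation_day
                if uninfected_initiation_day is None
                else uninfected_initiation_day,
                daily_mortality
                if uninfected_daily_mortality is None
                else uninfected_daily_mortality,
            )
        return cls(
            kind="biopesticide",
            coverage=coverage,
            virulence_infected=infected,
            virulence_uninfected=uninfected,
        )

    # -- serialization ------------------------------------------------------

    @classmethod
    def from_dict(cls, spec: dict[str, Any]) -> "Intervention":
        from .parameters import ConfigError

        spec = dict(spec)
        kind = spec.pop("kind", "none")
        coverage = spec.pop("coverage", 0.0)
        repellency = spec.pop("repellency", 0.0)
        init = spec.pop("initiation_day", None)
        dm = spec.pop("daily_mortality", None)
        uinit = spec.pop("uninfected_initiation_day", None)
        udm = spec.pop("uninfected_daily_mortality", None)
        if spec:
            raise ConfigError(
                f"unknown intervention key(s): {', '.join(sorted(spec))}"
            )
        if kind == "biopesticide":
            return cls.biopesticide(
                coverage,
                0.0 if init is None else init,
                0.0 if dm is None else dm,
                uinit,
                udm,
            )
        if kind == "instant_kill":
            return cls.instant_kill(coverage, repellency)
        return cls.none()

    def to_dict(self) -> dict[str, Any]:
        doc: dict[str, Any] = {"kind": self.kind, "coverage": self.coverage}
        if self.kind == "instant_kill":
            doc["repellency"] = self.repellency
        if self.kind == "biopesticide":
            assert self.virulence_infected is not None
            doc["initiation_day"] = self.virulence_infected.initiation_day
            doc["daily_mortality"] = self.virulence_infected.daily_mortality
            if self.virulence_uninfected != self.virulence_infected:
                assert self.virulence_uninfected is not None
                doc["uninfected_initiation_day"] = self.virulence_uninfected.initiation_day
                doc["uninfected_daily_mortality"] = self.virulence_uninfected.daily_mortality
        return doc

    @property
    def label(self) -> str:
        """Short human-readable tag used in tables and CSV output."""
        if self.kind == "none":
            return "untreated"
        if self.kind == "instant_kill":
            if self.repellency:
                return f"instant_kill(repellency={self.repellency:g})"
            return "instant_kill"
        assert self.virulence_infected is not None
        tag = (
            f"biopesticide(day={self.virulence_infected.initiation_day:g},"
            f"rate={self.virulence_infected.daily_mortality:g}"
        )
        if self.virulence_uninfected != self.virulence_infected:
            assert self.virulence_uninfected is not None
            tag += (
                f",uninfected_day={self.virulence_uninfected.initiation_day:g},"
                f"uninfected_rate={self.virulence_uninfected.daily_mortality:g}"
            )
        return tag + ")"

    # -- derived quantities -------------------------------------------------

    @property
    def effective_contact(self) -> float:
        """Per-human-blood-meal probability of being killed (instant-kill)
        or fungus-infected (biopesticide): ``coverage * (1 - repellency)``."""
        return self.coverage * (1.0 - self.repellency)

    def schedule_for(self, malaria_infected: bool) -> VirulenceSchedule:
        """Active virulence schedule given current malaria status."""
        if self.kind != "biopesticide":
            return VirulenceSchedule()
        assert self.virulence_infected is not None
        assert self.virulence_uninfected is not None
        return self.virulence_infected if malaria_infected else self.virulence_uninfected


def effective_contact_prob(iv: Intervention) -> float:
    """Functional alias for :attr:`Intervention.effective_contact`."""
    return iv.effective_contact
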