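"""Deterministic feeding-cycle model (FCM) for one mosquito type.

The adult female life is discretized into ``max_age_classes`` gonotrophic
cycles.  Within each cycle the mosquito (1) searches for a host for ``b``
days, (2) attacks a host chosen among non-human / non-infectious human /
infectious human, with pre- and post-bite attack mortality, (3) rests for
``eta`` days — the moment at which IRS products act: instant-kill chemicals
kill, biopesticides infect — and (4) searches ``phi`` days for an oviposition
site, laying ``L`` eggs if it survives.  Background mortality is a constant
hazard over the three activity segments.

A fungal infection takes its toll during the oviposition search — the
cycle's final flight, where "mortality" stands for death or the equivalent
cessation of feeding and reproduction, and strikes before any eggs are laid.
The infection clock is anchored at the midpoint of the resting period in
which the spores were picked up, and each cycle's charge is the virulence
schedule's hazard over the days-since-infection window spanned by that
cycle's oviposition-search segment (only the part past the initiation day
counts).

State is the pair (malaria age ``m``, fungal age ``l``) in whole cycles,
0 meaning uninfected.  The model propagates exact state probabilities
``v[i, m, l]`` forward and accumulates, per cycle, survival ``S_i``, expected
eggs ``F_i`` and expected infectious bites ``I_i`` (all conditional on being
alive at the start of cycle ``i``), plus the lifetime totals:

* ``phi_eggs   = sum_i F_i V_i`` — lifetime egg production (LRS proxy);
* ``u = sum_i I_i V_i`` — lifetime infectious bites (transmission proxy).

A bite is infectious when the malaria infection is old enough to have
completed sporogony: by default strictly more than ``sporogony_cycles``
cycles old (4 cycles = 11.4 d covers the 10.78-d sporogony, whereas 3 cycles
= 8.55 d does not); the ``infectious_at_m_equal_d`` switch selects the
inclusive boundary instead.

Headline comparative metrics:

* ``raib`` — proportionate reduction in average infectious bites per
  lifetime, ``1 - u_treated / u_untreated``; equals the proportionate EIR
  reduction under constant adult recruitment;
* ``selection_coefficient`` — proportionate lifetime-reproductive-success
  deficit of a treated mosquito type against the untreated susceptible
  reference, ``1 - phi_candidate / phi_reference``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .interventions import Intervention, fungal_survival
from .parameters import BiologyParams

__all__ = [
    "MosquitoState",
    "TransitionRecord",
    "FCMResult",
    "cycle_transition",
    "run_fcm",
    "raib",
    "selection_coefficient",
    "UndefinedMetricError",
]


class UndefinedMetricError(ZeroDivisionError):
    """The reference quantity of a relative metric is zero."""


@dataclass(frozen=True)
class MosquitoState:
    """State at the start of a feeding cycle: age class ``i`` (1-based) and
    infection ages ``m`` (malaria) and ``l`` (fungus), in whole cycles, with
    0 meaning uninfected."""

    age_class: int
    malaria_age: int = 0
    fungal_age: int = 0

    def __post_init__(self) -> None:
        if self.age_class < 1:
            raise ValueError(f"age_class must be >= 1, got {self.age_class!r}")
        if not 0 <= self.malaria_age < self.age_class:
            raise ValueError(
                f"malaria_age must satisfy 0 <= m < i, got m={self.malaria_age!r}"
            )
        if not 0 <= self.fungal_age < self.age_class:
            raise ValueError(
                f"fungal_age must satisfy 0 <= l < i, got l={self.fungal_age!r}"
            )


@dataclass(frozen=True)
class TransitionRecord:
    """One cycle's outcome for a single starting state (all quantities are
    conditional on being alive at the cycle start)."""

    eggs: float
    infectious_bites: float
    outcomes: dict[tuple[int, int], float]  # (m', l') -> probability
    death_prob: float

    @property
    def survival(self) -> float:
        return sum(self.outcomes.values())


def _oviposition_fungal_ages(l: int, bio: BiologyParams) -> tuple[float, float]:
    """Days-since-infection interval spanned by the oviposition-search
    segment of a cycle entered with fungal age ``l`` (``l = 0`` for an
    infection acquired during this cycle's rest).

    Infection is anchored at the midpoint of the resting segment of the
    exposure cycle; cycle ``c`` occupies absolute time ``[(c-1)w, cw)`` with
    the three segments laid back-to-back from the cycle start, so the
    oviposition search of the cycle with fungal age ``l`` spans infection
    ages ``[l w + eta/2, l w + eta/2 + phi]``.
    """
    start = l * bio.cycle_length + bio.resting_time / 2.0
    return (start, start + bio.oviposition_search_time)


def cycle_transition(
    state: MosquitoState,
    bio: BiologyParams,
    iv: Intervention,
    resistant: bool = False,
) -> TransitionRecord:
    """Exact one-cycle transition for a mosquito starting in ``state``.

    Event order: host search (background hazard) -> host choice -> pre-bite
    attack mortality -> bite (recorded as infectious if the host is human
    and sporogony is complete; malaria acquired on infectious humans) ->
    post-bite attack mortality and, for susceptibles under an instant-kill
    product after a human bite, insecticide kill -> rest (background hazard;
    fungal infection acquired here under a biopesticide) -> oviposition
    search (background hazard plus the fungal-infection charge, including a
    newly acquired infection past its initiation day) -> egg laying.
    Resistant mosquitoes are never killed by the chemical and never acquire
    the fungus but are otherwise identical.
    """
    if state.age_class > bio.max_age_classes:
        raise ValueError(
            f"age_class {state.age_class} exceeds max_age_classes "
            f"{bio.max_age_classes}"
        )
    m, l = state.malaria_age, state.fungal_age
    rB = bio.background_mortality_rate
    b, eta, phi = bio.host_search_time, bio.resting_time, bio.oviposition_search_time
    H = bio.nonhuman_host_prob
    p = bio.infectious_human_fraction
    a1 = bio.pre_bite_attack_mortality
    a2 = bio.post_bite_attack_mortality
    M = bio.malaria_infection_prob
    L = bio.eggs_per_laying
    contact = iv.effective_contact

    sb_search = math.exp(-rB * b)
    sb_rest = math.exp(-rB * eta)
    sb_ovi = math.exp(-rB * phi)

    host_probs = (H, (1.0 - H) * (1.0 - p), (1.0 - H) * p)
    infectious_when_biting = m >= bio.infectious_age_threshold

    eggs = 0.0
    bites = 0.0
    outcomes: dict[tuple[int, int], float] = {}

    def _fungal_ovi(fungal_age: int, malaria_now: bool) -> float:
        interval = _oviposition_fungal_ages(fungal_age, bio)
        return fungal_survival(*interval, iv.schedule_for(malaria_now))

    # host search
    alive = sb_search

    for h, p_host in enumerate(host_probs, start=1):
        if p_host == 0.0:
            continue
        human = h in (2, 3)
        at_bite = alive * p_host * (1.0 - a1)
        if human and infectious_when_biting:
            bites += at_bite  # recorded at the bite, before post-bite mortality
        # malaria acquisition branches: (probability, acquired?)
        if h == 3 and m == 0 and M > 0.0:
            mal_branches = [(M, True)]
            if M < 1.0:
                mal_branches.append((1.0 - M, False))
        else:
            mal_branches = [(1.0, False)]
        for p_mal, acquired_malaria in mal_branches:
            after_bite = at_bite * p_mal * (1.0 - a2)
            if (
                human
                and iv.kind == "instant_kill"
                and not resistant
                and contact > 0.0
            ):
                after_bite *= 1.0 - contact
            if after_bite == 0.0:
                continue
            malaria_now = (m > 0) or acquired_malaria
            after_rest = after_bite * sb_rest
            # fungal acquisition branches: (probability, acquired?)
            if (
                human
                and iv.kind == "biopesticide"
                and not resistant
                and l == 0
                and contact > 0.0
            ):
                fung_branches = [(contact, True)]
                if contact < 1.0:
                    fung_branches.append((1.0 - contact, False))
            else:
                fung_branches = [(1.0, False)]
            for p_fung, acquired_fungus in fung_branches:
                alive_end = after_rest * p_fung * sb_ovi
                if l >= 1:
                    alive_end *= _fungal_ovi(l, malaria_now)
                elif acquired_fungus:
                    alive_end *= _fungal_ovi(0, malaria_now)
                if alive_end == 0.0:
                    continue
                eggs += alive_end * L
                m_next = m + 1 if m > 0 else (1 if acquired_malaria else 0)
                l_next = l + 1 if l > 0 else (1 if acquired_fungus else 0)
                key = (m_next, l_next)
                outcomes[key] = outcomes.get(key, 0.0) + alive_end

    survival = sum(outcomes.values())
    return TransitionRecord(
        eggs=eggs,
        infectious_bites=bites,
        outcomes=outcomes,
        death_prob=1.0 - survival,
    )


@dataclass(frozen=True)
class FCMResult:
    """Per-age-class series and lifetime totals for one mosquito type under
    one intervention.  Arrays are indexed ``[i-1]`` for cycle ``i``; the
    per-cycle quantities ``S_i``, ``F_i``, ``I_i`` are conditional on being
    alive at the start of cycle ``i``."""

    state_probs: tuple[dict[tuple[int, int], float], ...]
    alive_probs: np.ndarray  # V_i
    cycle_survival: np.ndarray  # S_i
    cycle_eggs: np.ndarray  # F_i
    cycle_infectious_bites: np.ndarray  # I_i
    lifetime_eggs: float  # phi
    lifetime_infectious_bites: float  # u

    @property
    def n_cycles(self) -> int:
        return len(self.alive_probs)


def run_fcm(
    bio: BiologyParams, iv: Intervention, resistant: bool = False
) -> FCMResult:
    """Propagate state probabilities through all age classes.

    Starts from certainty of the uninfected state (``v[1, 0, 0] = 1``) and
    applies :func:`cycle_transition` to every reachable state; probability
    mass still alive after the last age class contributes nothing further.
    """
    lam = bio.max_age_classes
    V = np.zeros(lam)
    S = np.zeros(lam)
    F = np.zeros(lam)
    I = np.zeros(lam)
    states: list[dict[tuple[int, int], float]] = []

    v: dict[tuple[int, int], float] = {(0, 0): 1.0}
    for i in range(1, lam + 1):
        states.append(dict(v))
        Vi = sum(v.values())
        V[i - 1] = Vi
        if Vi <= 0.0:
            break
        v_next: dict[tuple[int, int], float] = {}
        surv_mass = eggs_mass = bites_mass = 0.0
        for (m, l), prob in v.items():
            rec = cycle_transition(MosquitoState(i, m, l), bio, iv, resistant)
            eggs_mass += prob * rec.eggs
            bites_mass += prob * rec.infectious_bites
            for key, q in rec.outcomes.items():
                v_next[key] = v_next.get(key, 0.0) + prob * q
                surv_mass += prob * q
        S[i - 1] = surv_mass / Vi
        F[i - 1] = eggs_mass / Vi
        I[i - 1] = bites_mass / Vi
        v = v_next

    phi_eggs = float(np.dot(F, V))
    u = float(np.dot(I, V))
    return FCMResult(
        state_probs=tuple(states),
        alive_probs=V,
        cycle_survival=S,
        cycle_eggs=F,
        cycle_infectious_bites=I,
        lifetime_eggs=phi_eggs,
        lifetime_infectious_bites=u,
    )


def raib(treated: FCMResult, untreated: FCMResult) -> float:
    """Proportionate reduction in average infectious bites per lifetime."""
    if untreated.lifetime_infectious_bites <= 0.0:
        raise UndefinedMetricError(
            "untreated lifetime infectious bites is zero; RAIB undefined"
        )
    return 1.0 - treated.lifetime_infectious_bites / untreated.lifetime_infectious_bites


def selection_coefficient(
    candidate: FCMResult, reference_untreated_susceptible: FCMResult
) -> float:
    """Proportionate LRS deficit of ``candidate`` against the untreated
    susceptible reference; zero means no selection for resistance."""
    if reference_untreated_susceptible.lifetime_eggs <= 0.0:
        raise UndefinedMetricError(
            "reference lifetime egg production is zero; selection coefficient undefined"
        )
    return 1.0 - candidate.lifetime_eggs / reference_untreated_susceptible.lifetime_eggs
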