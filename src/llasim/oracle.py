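"""Agent-based cohort simulator used as an independent cross-check.

Test support: this module re-creates the feeding-cycle event chain by direct
per-mosquito random sampling, sharing no computational code with the
deterministic model in :mod:`llasim.fcm` — every probability here is spelt
out from the biological parameters again.  It is deliberately simple,
vectorized across agents with numpy only for speed, and is not part of the
public modelling API.

Each agent walks through its cycles drawing Bernoulli outcomes for segment
survival (exponential survival against the composed hazard of each
segment), host choice, attack mortality, insecticide contact and infection
acquisition, accumulating eggs laid and infectious bites given.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .interventions import Intervention
from .parameters import BiologyParams

__all__ = ["CohortResult", "simulate_cohort"]


@dataclass(frozen=True)
class CohortResult:
    """Sample summaries of a simulated cohort of ``n`` mosquitoes."""

    n: int
    mean_eggs: float
    se_eggs: float
    mean_infectious_bites: float
    se_infectious_bites: float
    alive_fractions: np.ndarray  # fraction alive at the start of each cycle
    se_alive_fractions: np.ndarray


def _fungal_log_survival(
    ages: np.ndarray, initiation: float, hazard: float, width: float
) -> np.ndarray:
    """Log fungal survival over the oviposition window ``[age, age+width]``
    days since infection, for a schedule initiating at ``initiation`` with
    constant ``hazard`` (may be inf)."""
    overlap = np.clip(ages + width - np.maximum(ages, initiation), 0.0, None)
    with np.errstate(invalid="ignore"):
        out = -hazard * overlap
    # inf * 0 -> nan; zero overlap means no exposure at all
    out = np.where(overlap <= 0.0, 0.0, out)
    return out


def simulate_cohort(
    n: int,
    seed: int,
    bio: BiologyParams,
    iv: Intervention,
    resistant: bool = False,
) -> CohortResult:
    """Simulate ``n`` adult females from emergence to death or the last
    tracked age class and return sample means with standard errors."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    rng = np.random.default_rng(seed)

    rB = bio.background_mortality_rate
    b, eta, phi = bio.host_search_time, bio.resting_time, bio.oviposition_search_time
    w = bio.cycle_length
    H = bio.nonhuman_host_prob
    p = bio.infectious_human_fraction
    a1 = bio.pre_bite_attack_mortality
    a2 = bio.post_bite_attack_mortality
    M = bio.malaria_infection_prob
    L = bio.eggs_per_laying
    lam = bio.max_age_classes
    threshold = bio.infectious_age_threshold
    contact = iv.effective_contact

    p_search = math.exp(-rB * b)
    p_rest = math.exp(-rB * eta)
    p_ovi_bg = math.exp(-rB * phi)

    if iv.kind == "biopesticide":
        sched_inf = iv.schedule_for(True)
        sched_uninf = iv.schedule_for(False)
    else:
        sched_inf = sched_uninf = None

    alive = np.ones(n, dtype=bool)
    malaria_age = np.zeros(n, dtype=np.int64)
    fungal_age = np.zeros(n, dtype=np.int64)
    fungus_infected = np.zeros(n, dtype=bool)
    eggs = np.zeros(n)
    bites = np.zeros(n)
    alive_frac = np.zeros(lam)

    for _cycle in range(1, lam + 1):
        alive_frac[_cycle - 1] = alive.mean()
        if not alive.any():
            break
        # host search: background hazard only
        alive &= rng.random(n) < p_search
        # host choice: 0 non-human, 1 non-infectious human, 2 infectious human
        u = rng.random(n)
        host = np.where(u < H, 0, np.where(u < H + (1 - H) * (1 - p), 1, 2))
        # pre-bite attack mortality
        alive &= rng.random(n) < 1.0 - a1
        # the bite: infectious if sporogony complete; recorded before any
        # post-bite mortality
        biting = alive & (host > 0)
        bites += (biting & (malaria_age >= threshold)).astype(float)
        acquired_malaria = (
            biting & (host == 2) & (malaria_age == 0) & (rng.random(n) < M)
        )
        # post-bite attack mortality, then the insecticide
        alive &= rng.random(n) < 1.0 - a2
        if iv.kind == "instant_kill" and not resistant and contact > 0.0:
            alive &= ~((alive & (host > 0)) & (rng.random(n) < contact))
        # rest: background hazard; biopesticide exposure happens here
        alive &= rng.random(n) < p_rest
        acquired_fungus = np.zeros(n, dtype=bool)
        if iv.kind == "biopesticide" and not resistant and contact > 0.0:
            acquired_fungus = (
                alive & (host > 0) & ~fungus_infected & (rng.random(n) < contact)
            )
        # oviposition search: background hazard plus the fungal charge for
        # the days-since-infection window this segment spans (anchor at the
        # mid-rest pick-up)
        p_ovi = np.full(n, p_ovi_bg)
        if iv.kind == "biopesticide":
            exposed = alive & (fungus_infected | acquired_fungus)
            if exposed.any():
                ages = np.where(
                    acquired_fungus, 0, fungal_age
                ) * w + eta / 2.0
                malaria_now = (malaria_age > 0) | acquired_malaria
                log_s = np.zeros(n)
                for sched, mask in (
                    (sched_inf, malaria_now),
                    (sched_uninf, ~malaria_now),
                ):
                    sel = exposed & mask
                    if sel.any():
                        log_s[sel] = _fungal_log_survival(
                            ages[sel],
                            sched.initiation_day,
                            sched.hazard,
                            phi,
                        )
                p_ovi = p_ovi * np.exp(log_s)
        alive &= rng.random(n) < p_ovi
        eggs += np.where(alive, L, 0.0)
        # advance infection clocks
        malaria_age = np.where(
            malaria_age > 0, malaria_age + 1, np.where(acquired_malaria, 1, 0)
        )
        fungal_age = np.where(
            fungus_infected, fungal_age + 1, np.where(acquired_fungus, 1, 0)
        )
        fungus_infected |= acquired_fungus

    se = lambda x: float(np.std(x, ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    p_alive = alive_frac
    se_alive = np.sqrt(np.clip(p_alive * (1 - p_alive), 0, None) / n)
    return CohortResult(
        n=n,
        mean_eggs=float(eggs.mean()),
        se_eggs=se(eggs),
        mean_infectious_bites=float(bites.mean()),
        se_infectious_bites=se(bites),
        alive_fractions=p_alive,
        se_alive_fractions=se_alive,
    )
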