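"""Population model: spread of a resistance allele under sustained treatment.

Discrete time, one period per gonotrophic cycle.  The population is a
composition over (genotype, age class) cells; genotypes are ``ss`` (0),
``sr`` (1) and ``rr`` (2) at a single resistance locus, and the phenotype of
heterozygotes follows the dominance indicator ``d`` (1: resistant, 0:
susceptible).  Resistance is binary and cost-free: resistant-phenotype
mosquitoes are unaffected by the treatment and otherwise identical.

Assumptions carried over from the single-mosquito model's framing:

* density dependence acts on larvae, so a constant *count* of new adults is
  recruited each period — eggs determine only the genotype mix of recruits,
  never their number;
* the starting population has the size and stationary age structure reached
  after sustained use of the treatment on an all-susceptible population;
* recruits emerging in period ``n`` hatched from eggs laid ``recruitment_lag``
  periods earlier, with genotype proportions given by random union of
  maternal gametes (from the egg-laying females) and paternal gametes (from
  the adult male pool at laying, weighted by the male fitness factors).

Outputs per period: genotype fractions ``G_g``, resistant-phenotype fraction
``R = G_rr + d G_sr``, population size ``W`` relative to the initial
(treated) population, mean infectious bites per mosquito ``M``, and the
population bite output ``Q`` relative to an untreated susceptible population
(``Q = M W J / q`` where ``J`` scales the treated to the untreated
population size and ``q`` is the untreated per-capita per-period bite rate).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .fcm import FCMResult, run_fcm
from .interventions import Intervention
from .parameters import BiologyParams, PopulationParams

__all__ = [
    "GENOTYPES",
    "PMState",
    "PMTrajectory",
    "ExtinctionError",
    "DegeneratePopulationError",
    "stable_population",
    "recruit_genotypes",
    "step_population",
    "run_pm",
]

GENOTYPES = ("ss", "sr", "rr")


class ExtinctionError(RuntimeError):
    """No eggs were laid in a period; the population has collapsed."""


class DegeneratePopulationError(RuntimeError):
    """The survival schedule admits no living population."""


def phenotype_indices(dominance: int) -> tuple[int, int, int]:
    """Map genotype index -> phenotype index (0 susceptible, 1 resistant)."""
    return (0, 1 if dominance == 1 else 0, 1)


@dataclass
class PMState:
    """Population composition at the start of a period.

    ``abundance[g, i]`` is the absolute abundance of genotype ``g`` in age
    class ``i+1``, in units of the initial population (which sums to 1).
    ``egg_queue`` holds, oldest first, one entry per pending recruitment
    period: the per-genotype egg totals laid that period together with a
    snapshot of the adult genotype pool at laying (the mating pool).
    """

    period: int
    abundance: np.ndarray  # shape (3, lambda)
    egg_queue: deque  # entries: (egg_totals (3,), male_pool (3,))
    recruit_count: float

    @property
    def population_scale(self) -> float:
        return float(self.abundance.sum())

    @property
    def genotype_fractions(self) -> np.ndarray:
        total = self.abundance.sum()
        return self.abundance.sum(axis=1) / total

    @property
    def composition(self) -> np.ndarray:
        """Proportion of the population in each (genotype, age) cell."""
        return self.abundance / self.abundance.sum()


@dataclass(frozen=True)
class PMTrajectory:
    """Per-period series from a population run."""

    periods: np.ndarray
    genotype_fractions: np.ndarray  # shape (n, 3)
    resistant_fraction: np.ndarray  # R_n
    population_scale: np.ndarray  # W_n
    mean_infectious_bites: np.ndarray  # M_n
    relative_bite_output: np.ndarray  # Q_n
    J: float
    q: float

    def time_to_failure(self, threshold: float = 0.5) -> int | None:
        """First period whose bite output exceeds ``threshold`` times the
        untreated level, or ``None`` if control holds throughout."""
        exceeded = np.nonzero(self.relative_bite_output > threshold)[0]
        return int(self.periods[exceeded[0]]) if exceeded.size else None

    def time_to_resistance(self, fraction: float = 0.5) -> int | None:
        """First period with at least ``fraction`` resistant phenotypes."""
        hit = np.nonzero(self.resistant_fraction >= fraction)[0]
        return int(self.periods[hit[0]]) if hit.size else None


def stable_population(
    fcm_treated: FCMResult,
    fcm_untreated: FCMResult,
    params: PopulationParams,
) -> tuple[np.ndarray, float, float]:
    """Initial composition, relative size ``J`` and per-period recruit count.

    Under constant recruitment the stationary abundance of age class ``i``
    is proportional to the probability ``V_i`` of surviving to it, so the
    treated susceptible population settles at age shares ``V_i / sum V``,
    with total size ``J = sum V_treated / sum V_untreated`` relative to the
    untreated base.  The initial genotype split is applied uniformly across
    ages.  Returns ``(abundance, J, recruit_count)`` with abundance summing
    to 1.
    """
    V_t = fcm_treated.alive_probs
    V_u = fcm_untreated.alive_probs
    total_t = V_t.sum()
    if total_t <= 0.0:
        raise DegeneratePopulationError("treated survival schedule is all zero")
    J = float(total_t / V_u.sum())
    age_shares = V_t / total_t
    fractions = np.asarray(params.initial_genotype_fractions)
    abundance = np.outer(fractions, age_shares)
    recruit_count = float(1.0 / total_t)  # age-1 share of a unit population
    return abundance, J, recruit_count


def recruit_genotypes(
    egg_totals: np.ndarray,
    male_pool: np.ndarray,
    male_fitness: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Genotype proportions among offspring by random union of gametes.

    Maternal gamete frequencies come from the per-genotype egg totals;
    paternal frequencies from the adult male pool weighted by the male
    fitness factors.  Mendelian segregation: heterozygotes contribute half
    of each allele.
    """
    eggs = np.asarray(egg_totals, dtype=float)
    if np.any(eggs < 0):
        raise ValueError("egg totals must be non-negative")
    total = eggs.sum()
    if total <= 0.0:
        raise ExtinctionError("no eggs laid; population collapse")
    maternal_r = (0.5 * eggs[1] + eggs[2]) / total
    males = np.asarray(male_pool, dtype=float) * np.asarray(male_fitness, dtype=float)
    males_total = males.sum()
    if males_total <= 0.0:
        raise ExtinctionError("no males in the mating pool")
    paternal_r = (0.5 * males[1] + males[2]) / males_total
    pm, pp = maternal_r, paternal_r
    return np.array(
        [
            (1.0 - pm) * (1.0 - pp),
            pm * (1.0 - pp) + (1.0 - pm) * pp,
            pm * pp,
        ]
    )


def _per_genotype(fcm_by_phenotype: tuple[FCMResult, FCMResult], dominance: int):
    phen = phenotype_indices(dominance)
    return tuple(fcm_by_phenotype[k] for k in phen)


def step_population(
    state: PMState,
    fcm_by_genotype: tuple[FCMResult, FCMResult, FCMResult],
    params: PopulationParams,
) -> PMState:
    """Advance the population one period.

    Eggs laid this period (with the current mating pool) join the
    recruitment queue; every cohort ages one class under its genotype's
    survival schedule; the cohort emerging from eggs laid
    ``recruitment_lag`` periods ago enters age class 1 at the constant
    recruit count.
    """
    N = state.abundance
    eggs = np.array(
        [float(N[g] @ fcm_by_genotype[g].cycle_eggs) for g in range(3)]
    )
    pool = state.genotype_fractions
    state.egg_queue.append((eggs, pool))
    egg_totals, laying_pool = state.egg_queue.popleft()

    new = np.zeros_like(N)
    for g in range(3):
        S = fcm_by_genotype[g].cycle_survival
        new[g, 1:] = N[g, :-1] * S[:-1]
    recruits = recruit_genotypes(
        egg_totals, laying_pool, params.male_fitness_factors
    )
    new[:, 0] = state.recruit_count * recruits
    return PMState(
        period=state.period + 1,
        abundance=new,
        egg_queue=state.egg_queue,
        recruit_count=state.recruit_count,
    )


def run_pm(
    bio: BiologyParams,
    iv: Intervention,
    params: PopulationParams,
) -> PMTrajectory:
    """Track genotype frequencies and bite output over ``params.n_periods``.

    Builds the three per-genotype feeding-cycle results (susceptible
    phenotype under treatment, resistant phenotype, untreated reference),
    starts from the treated-susceptible stationary population seeded with
    the initial genotype fractions, and iterates :func:`step_population`.
    """
    fcm_u = run_fcm(bio, Intervention.none(), resistant=False)
    fcm_s = run_fcm(bio, iv, resistant=False)
    fcm_r = run_fcm(bio, iv, resistant=True)
    fcm_by_genotype = _per_genotype((fcm_s, fcm_r), params.dominance)

    abundance, J, recruit_count = stable_population(fcm_s, fcm_u, params)
    V_u = fcm_u.alive_probs
    q = float((V_u / V_u.sum()) @ fcm_u.cycle_infectious_bites)

    # pre-fill the recruitment pipeline with the equilibrium egg output
    eggs0 = np.array(
        [float(abundance[g] @ fcm_by_genotype[g].cycle_eggs) for g in range(3)]
    )
    pool0 = abundance.sum(axis=1) / abundance.sum()
    queue = deque(
        (eggs0.copy(), pool0.copy()) for _ in range(max(params.recruitment_lag, 1))
    )
    state = PMState(
        period=1, abundance=abundance, egg_queue=queue, recruit_count=recruit_count
    )

    n = params.n_periods
    G = np.zeros((n, 3))
    R = np.zeros(n)
    W = np.zeros(n)
    M = np.zeros(n)
    Q = np.zeros(n)
    d = params.dominance
    for k in range(n):
        N = state.abundance
        total = N.sum()
        G[k] = N.sum(axis=1) / total
        R[k] = G[k, 2] + d * G[k, 1]
        W[k] = total
        M[k] = (
            sum(float(N[g] @ fcm_by_genotype[g].cycle_infectious_bites) for g in range(3))
            / total
        )
        Q[k] = M[k] * W[k] * J / q
        if k < n - 1:
            state = step_population(state, fcm_by_genotype, params)

    return PMTrajectory(
        periods=np.arange(1, n + 1),
        genotype_fractions=G,
        resistant_fraction=R,
        population_scale=W,
        mean_infectious_bites=M,
        relative_bite_output=Q,
        J=J,
        q=q,
    )
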