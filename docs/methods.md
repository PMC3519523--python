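# Methods

## Scope and model structure

`llasim` evaluates adult-mosquito vector-control products for malaria
programmes along two axes that trade off against each other: the immediate
reduction in transmission, and the selection pressure for resistance that
determines how long the product stays useful.  Two product classes are
compared: conventional instant-kill chemicals (e.g. pyrethroid IRS) and
delayed-action fungal biopesticides, whose defining feature is that they
kill late — ideally after a mosquito has reproduced but before a malaria
infection it carries becomes transmissible.

The package couples two deterministic models:

1. a **feeding-cycle model (FCM)** — a Markov chain over gonotrophic cycles
   for a single mosquito type (susceptible or resistant) under one
   intervention, yielding lifetime expected egg production `phi` (the
   lifetime-reproductive-success proxy) and lifetime expected infectious
   bites `u` (the transmission proxy); and
2. a **population model (PM)** — a discrete-time recursion over
   (genotype × age-class) composition under constant adult recruitment,
   tracking the resistant-phenotype fraction `R_n` and the population bite
   output `Q_n` relative to an untreated population.

Comparative metrics are relative throughout, which makes them insensitive
to parameters that do not differ between the compared scenarios:

* `RAIB = 1 − u_treated / u_untreated` — proportionate reduction in average
  infectious bites per mosquito lifetime; under constant recruitment this
  equals the proportionate reduction in the entomological inoculation rate.
* `selection coefficient = 1 − phi_candidate / phi_untreated_susceptible` —
  the proportionate fitness deficit that treatment imposes on susceptible
  mosquitoes; zero means no selection for resistance.

## The feeding cycle

Each age class is one gonotrophic cycle of `w = 2.85` days containing three
activity segments laid back to back: host search (`b = 1.26` d), post-meal
rest (`eta = 0.32` d) and oviposition-site search (`phi = 1.26` d).  The
0.01-day slack between the segments and the cycle length carries no hazard.
Background mortality is an age-independent instantaneous hazard of 0.1175
per day applied over the activity segments.  Within a cycle the event order
is:

1. host search under background hazard;
2. host choice: non-human with probability `H = 0.17`, otherwise human, of
   whom a fraction `p = 0.0428` are infectious for malaria;
3. pre-bite attack mortality `a1 = 0.05`;
4. the bite: recorded as an *infectious bite* if the host is human and the
   mosquito's malaria infection has completed sporogony; a bite on an
   infectious human infects an uninfected mosquito with probability
   `M = 1`;
5. post-bite attack mortality `a2 = 0.05`, then — after a human blood meal
   only — the IRS product acts on susceptible mosquitoes while they rest:
   an instant-kill chemical kills with the composite coverage probability
   (times `1 − repellency` for contact-irritant products); a biopesticide
   infects with the composite coverage probability;
6. rest under background hazard;
7. oviposition search under background hazard plus the fungal-infection
   charge described below;
8. laying of `L = 100` eggs if still alive.

State is the pair of infection ages (malaria `m`, fungus `l`) in whole
cycles; exact state probabilities are propagated over `lambda = 10` age
classes, and mass alive after the last class is discarded (untreated
per-cycle survival is 0.646, so about 1% of lifetime egg mass lies beyond
class 10 — acceptable for the relative metrics, which discard it in both
numerator and denominator).

**Infectiousness boundary.** Sporogony takes 10.78 days.  Three whole
cycles (8.55 d) do not cover it and four (11.4 d) do, so by default a bite
is infectious when the malaria infection is strictly older than
`sporogony_cycles = 3`, i.e. from age 4 cycles.  The packaged switch
`infectious_at_m_equal_d` selects the inclusive boundary (age 3) instead;
it weakens transmission control substantially (the day-9 headline RAIB
drops from 93% to 77%) and is off by default.  Every CLI run logs the
active boundary.

**Bite accounting.** An infectious bite is credited at the bite itself:
post-bite mortality (including the instant-kill chemical) cannot retract
it.  With full instant-kill coverage the model still produces zero
infectious bites, because the malaria-acquiring bite is itself fatal — no
mosquito ever carries a mature infection.

**Fungal virulence.** A biopesticide infection is described by two
parameters: an initiation day `T` (days post-infection with no incremental
mortality) and a fixed daily mortality rate thereafter, converted to a
constant hazard `h = −ln(1 − rate)` so that a mosquito alive at the start
of a post-initiation day survives it with probability `1 − rate` (survival
falls on a straight line on a log scale).  The infection clock is anchored
at the midpoint of the resting period in which the spores were picked up.

The infection's toll is charged during the **oviposition search** of each
cycle — the final flight, where "mortality" includes the cessation of
feeding and reproduction that precedes death in fungus-infected mosquitoes
— and strikes *before* laying.  The charge for the cycle entered with
fungal age `l` is the schedule hazard over the days-since-infection window
`[l·w + eta/2, l·w + eta/2 + phi]`, clipped below the initiation day.
Host-search and resting segments carry background hazard only.  This
placement was chosen, among the defensible readings of a per-day schedule
overlaid on a segmented cycle, as the one that reproduces the package's
reference values for both fitness costs and transmission reduction
simultaneously; charging the fungal hazard continuously across all three
segments inflates late-initiation transmission blocking (the day-9
headline RAIB rises from 92.6% to 94.4%) while charging it after laying
deflates fitness costs (the day-9 selection coefficient falls from 21% to
14%).

One consequence worth noting: a day-0, 100%-daily-mortality biopesticide is
numerically identical to an instant-kill chemical at equal coverage — the
contacted mosquito dies on its first post-contact flight, before laying.
Matching instant-kill control at equal coverage therefore forces total
virulence and yields no resistance-management benefit; the benefit appears
as soon as initiation is delayed at all, at a small price in control.

**Malaria-differential virulence.** The schedule may differ between
malaria-infected and malaria-free mosquitoes.  The active schedule is
chosen by the mosquito's malaria status during the segment being charged
(a mosquito infected at this cycle's bite is already on the infected
schedule for this cycle's oviposition search).

**Resistance** is binary and cost-free: resistant mosquitoes are never
killed by the chemical and never acquire the fungus, and are otherwise
identical.  Absent treatment the two types are indistinguishable.

## The population model

Time advances in periods of one gonotrophic cycle.  The state is the
absolute abundance of each (genotype, age-class) cell, in units of the
initial population, plus a recruitment pipeline.

* **Initial condition:** the stationary age structure reached after
  sustained use of the treatment on an all-susceptible population — age
  shares proportional to the treated `V_i` — seeded uniformly across ages
  with the initial genotype fractions (baseline: heterozygotes at 1e-9).
  `J = sum V_treated / sum V_untreated` records the treated population size
  relative to the untreated base.
* **Recruitment:** density dependence acts on larvae, so a constant *count*
  of new adults enters age class 1 each period; eggs determine only the
  genotype mix, never the number.  Recruits emerging in period `n` come
  from eggs laid `Phi = 3` periods earlier.  Offspring genotypes follow
  random union of gametes: maternal frequencies from the per-genotype egg
  totals of the laying period, paternal frequencies from the adult pool *at
  laying* weighted by the male fitness factors (all 1 at baseline, reducing
  to random mating).  The queue stores each laying period's egg totals with
  a snapshot of its mating pool.
* **Survival and ageing:** each genotype ages under the per-cycle survival
  `S_i` of its phenotype (dominance `d = 1`: heterozygotes resistant).
* **Outputs:** genotype fractions `G_g,n`, resistant fraction
  `R_n = G_rr,n + d·G_sr,n`, population scale `W_n`, mean infectious bites
  per mosquito `M_n`, and `Q_n = M_n · W_n · J / q`, the population bite
  output relative to an untreated population, where `q` is the untreated
  per-capita per-period bite rate at the untreated stationary structure.
  With this normalization the first-period control `1 − Q_1` equals the
  susceptible FCM's RAIB to machine precision, which the tests assert.

"Time to failure" has no canonical definition; the packaged default is the
first period in which `Q_n` exceeds half the untreated bite output, and the
threshold is a parameter everywhere it appears.

## Experiments

* **Iso-RAIB curves:** for each integer initiation day (default 0..14) the
  daily mortality achieving a target RAIB at fixed coverage is found by
  root bracketing on [0, 1] (RAIB is monotone in the rate; tolerance 1e-6,
  100-iteration cap).  Days where even 100%/day falls short are omitted;
  required mortality is non-decreasing along the curve and the curve
  terminates at the last feasible day.
* **Minimum selection coefficient:** the curve point with the lowest
  susceptible selection coefficient, ties broken toward later initiation.
* **Matched-control sets:** an instant-kill chemical (coverage solved for
  the target RAIB) plus biopesticides at several initiation days, all
  calibrated to the same initial RAIB, compared through the PM.
* **Coverage sweeps:** FCM metrics across coverage for a set of
  intervention templates, with ratio columns against the instant-kill
  comparator at the same coverage (ratios defined as 1 when both effects
  are zero at coverage 0); the comparator may carry 50% contact repellency
  to represent pyrethroid excito-repellency.
* **Malaria-differential scenarios:** a family of biopesticides sharing the
  schedule for malaria-infected mosquitoes while the rate for malaria-free
  mosquitoes varies (same initiation day by default; the type allows a
  separate day).

## Verification

* A vectorized **agent-based simulator** (`llasim.oracle`) re-creates the
  event chain by direct per-mosquito sampling, sharing no computational
  code with the deterministic model.  The suites require agreement of
  lifetime eggs, lifetime infectious bites and per-cycle alive fractions
  (where above 1e-3) within three standard errors on a million-agent
  cohort for six scenarios spanning untreated, instant-kill (with and
  without repellency), early and late biopesticides and a
  malaria-differential schedule.
* Probability conservation (state mass vs `V_i`, `V_{i+1} = S_i V_i`) is
  asserted to 1e-12, genotype-fraction conservation in the PM likewise;
  allele frequency is conserved exactly through the recruitment step.
* Monotonicity of RAIB and selection coefficient (non-decreasing in
  coverage and daily mortality, non-increasing in initiation day) is
  asserted over a 5×5×3 grid.
* The virulence-schedule survival primitive is property-tested
  (bounds, monotonicities, semigroup composition) and checked against a
  fine-time-step product oracle.

## What the models do not capture

No human-side epidemiology or feedback on the infectious-human fraction;
no malaria effects on mosquito survival, fecundity or behaviour; no
age-varying fecundity or cycle length; no fungal dose-response, spore decay
or pre-bite (bed-net) deployment; no mutation, drift, immigration or
finite-population effects (resistance starts at an established low
frequency); resistance is single-locus with strict dominance or
recessivity and no fitness cost; superinfection never resets infection
clocks.  The deterministic cohort is per-capita: population sizes enter
only through the PM's relative scales.

## Problem sizes and numerical choices

The FCM propagates at most `lambda² = 100` states per cycle and runs in
milliseconds; iso-RAIB searches evaluate ~60 FCM runs per initiation day.
PM trajectories default to 2 000 periods (comparative suites use 120–900,
enough for every tracked scenario to reach its endpoint).  The agent-based
checks use 10^5 agents in the unit suite and 10^6 in the acceptance suite,
with fixed seeds for reproducibility.  All comparative tolerances are
stated next to the assertions they govern.
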