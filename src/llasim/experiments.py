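"""Comparative analyses: iso-RAIB virulence curves, selection-minimizing
virulence, coverage sweeps against instant-kill chemicals (with or without
contact repellency), matched-control trajectory comparisons, and
malaria-differential virulence scenarios.

All searches exploit the monotonicity of the EIR-reduction metric (RAIB) in
the daily mortality rate: the rate achieving a target RAIB at a given
initiation day and coverage is found by root bracketing on [0, 1].
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .fcm import FCMResult, raib, run_fcm, selection_coefficient
from .interventions import Intervention, VirulenceSchedule
from .parameters import BiologyParams, PopulationParams
from .population import PMTrajectory, run_pm

__all__ = [
    "VirulenceGrid",
    "IsoRaibPoint",
    "InfeasibleError",
    "iso_raib_curve",
    "min_selection_coefficient",
    "calibrate_matching_virulence",
    "matched_control_set",
    "coverage_sweep",
    "DifferentialResult",
    "differential_virulence_run",
]


class InfeasibleError(RuntimeError):
    """The requested control target cannot be reached; the message names the
    binding constraint."""


@dataclass(frozen=True)
class VirulenceGrid:
    """Search grid over two-parameter virulence schedules at one coverage."""

    coverage: float
    initiation_days: tuple[int, ...] = tuple(range(15))
    mortality_tol: float = 1e-6

    def __post_init__(self) -> None:
        if not self.initiation_days:
            raise ValueError("initiation_days must be non-empty")
        if not 0.0 < self.mortality_tol <= 0.01:
            raise ValueError("mortality_tol must be in (0, 0.01]")
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must be in [0, 1]")


@dataclass(frozen=True)
class IsoRaibPoint:
    """A virulence combination achieving the target RAIB, with the fitness
    cost it imposes on susceptible mosquitoes."""

    initiation_day: float
    daily_mortality: float
    selection_coefficient: float


def _untreated(bio: BiologyParams) -> FCMResult:
    return run_fcm(bio, Intervention.none())


def _biopesticide_raib(
    coverage: float, day: float, dm: float, bio: BiologyParams, ref: FCMResult
) -> float:
    return raib(run_fcm(bio, Intervention.biopesticide(coverage, day, dm)), ref)


def iso_raib_curve(
    target_raib: float,
    grid: VirulenceGrid,
    bio: BiologyParams,
    *,
    _reference: FCMResult | None = None,
) -> list[IsoRaibPoint]:
    """Daily mortality achieving ``target_raib`` at each feasible initiation
    day of the grid, with the susceptible selection coefficient attached.

    Days where even 100% daily mortality falls short are omitted; an empty
    list means the target is unreachable everywhere on the grid.
    """
    if not 0.0 < target_raib < 1.0:
        raise ValueError("target_raib must be in (0, 1)")
    ref = _reference if _reference is not None else _untreated(bio)
    points: list[IsoRaibPoint] = []
    for day in grid.initiation_days:
        f = lambda dm: _biopesticide_raib(grid.coverage, day, dm, bio, ref) - target_raib
        if f(1.0) < 0.0:
            continue  # unreachable even at total daily mortality
        dm = float(brentq(f, 0.0, 1.0, xtol=grid.mortality_tol, maxiter=100))
        fit = run_fcm(bio, Intervention.biopesticide(grid.coverage, day, dm))
        points.append(
            IsoRaibPoint(
                initiation_day=day,
                daily_mortality=dm,
                selection_coefficient=selection_coefficient(fit, ref),
            )
        )
    return points


def min_selection_coefficient(
    target_raib: float,
    coverage: float,
    grid: VirulenceGrid | None = None,
    bio: BiologyParams | None = None,
) -> IsoRaibPoint:
    """The iso-RAIB curve point with the lowest selection coefficient.

    Ties break toward the later initiation day (the more resistance-sparing
    schedule).  Raises :class:`InfeasibleError` when no virulence
    combination reaches the target at this coverage.
    """
    bio = bio or BiologyParams()
    if grid is None:
        grid = VirulenceGrid(coverage=coverage)
    elif grid.coverage != coverage:
        grid = dataclasses.replace(grid, coverage=coverage)
    curve = iso_raib_curve(target_raib, grid, bio)
    if not curve:
        raise InfeasibleError(
            f"RAIB {target_raib:g} is unreachable at coverage {coverage:g}: "
            "even immediate 100% daily mortality falls short on every "
            "initiation day of the grid"
        )
    return min(curve, key=lambda p: (p.selection_coefficient, -p.initiation_day))


def calibrate_matching_virulence(
    reference: Intervention,
    day: float,
    coverage: float,
    bio: BiologyParams,
    tol: float = 1e-6,
) -> Intervention:
    """Biopesticide with initiation ``day`` whose RAIB matches ``reference``'s.

    The daily mortality rate is bracketed on [0, 1]; an unreachable
    reference RAIB raises :class:`InfeasibleError`.
    """
    ref_fcm = _untreated(bio)
    target = raib(run_fcm(bio, reference), ref_fcm)
    if target <= 0.0:
        return Intervention.biopesticide(coverage, day, 0.0)
    f = lambda dm: _biopesticide_raib(coverage, day, dm, bio, ref_fcm) - target
    top = f(1.0)
    if top < -tol:
        raise InfeasibleError(
            f"reference RAIB {target:.4f} unreachable by a day-{day:g} "
            f"biopesticide at coverage {coverage:g} (max shortfall {-top:.4f})"
        )
    dm = 1.0 if top <= 0.0 else float(brentq(f, 0.0, 1.0, xtol=tol, maxiter=100))
    return Intervention.biopesticide(coverage, day, dm)


def matched_control_set(
    bio: BiologyParams,
    target_raib: float = 0.90,
    coverage: float = 0.8,
    initiation_days: tuple[int, ...] = (0, 5, 9),
    tol: float = 1e-6,
) -> list[Intervention]:
    """An instant-kill chemical plus biopesticides all calibrated to the same
    initial RAIB: the chemical's coverage and each biopesticide's daily
    mortality (at the given coverage) are solved for ``target_raib``."""
    ref = _untreated(bio)
    f_ik = lambda c: raib(run_fcm(bio, Intervention.instant_kill(c)), ref) - target_raib
    if f_ik(1.0) < 0.0:
        raise InfeasibleError(
            f"instant-kill cannot reach RAIB {target_raib:g} at any coverage"
        )
    ik_cov = float(brentq(f_ik, 0.0, 1.0, xtol=tol, maxiter=100))
    out = [Intervention.instant_kill(ik_cov)]
    grid = VirulenceGrid(coverage=coverage, mortality_tol=tol)
    curve = {
        p.initiation_day: p
        for p in iso_raib_curve(target_raib, grid, bio, _reference=ref)
    }
    for day in initiation_days:
        if day not in curve:
            raise InfeasibleError(
                f"RAIB {target_raib:g} unreachable at initiation day {day} "
                f"and coverage {coverage:g}"
            )
        out.append(
            Intervention.biopesticide(coverage, day, curve[day].daily_mortality)
        )
    return out


def coverage_sweep(
    ivs: list[Intervention],
    coverages: np.ndarray | list[float],
    bio: BiologyParams,
) -> pd.DataFrame:
    """FCM metrics for each intervention template across coverage values.

    Each template is re-evaluated with its coverage replaced by the sweep
    value.  Rows carry RAIB, the selection coefficient, the LRS ratios
    against the untreated and the instant-kill comparator, and the ratio of
    bite reductions against the instant-kill comparator at the same
    coverage (1 when both reductions are zero).  Exactly one instant-kill
    template is expected for the comparator columns; without one those
    columns are NaN.
    """
    ref = _untreated(bio)
    comparators = [iv for iv in ivs if iv.kind == "instant_kill"]
    comparator = comparators[0] if len(comparators) == 1 else None
    rows = []
    for cov in coverages:
        if not 0.0 <= cov <= 1.0:
            raise ValueError(f"coverage {cov!r} outside [0, 1]")
        ik_metrics = None
        if comparator is not None:
            ik_fit = run_fcm(bio, dataclasses.replace(comparator, coverage=cov))
            ik_metrics = (raib(ik_fit, ref), ik_fit.lifetime_eggs)
        for iv in ivs:
            fit = run_fcm(bio, dataclasses.replace(iv, coverage=cov))
            rb = raib(fit, ref)
            row = {
                "coverage": float(cov),
                "intervention": iv.label,
                "raib": rb,
                "selection_coefficient": selection_coefficient(fit, ref),
                "lrs_ratio_untreated": fit.lifetime_eggs / ref.lifetime_eggs,
                "lrs_ratio_instant_kill": np.nan,
                "raib_ratio_instant_kill": np.nan,
            }
            if ik_metrics is not None:
                ik_raib, ik_phi = ik_metrics
                row["lrs_ratio_instant_kill"] = fit.lifetime_eggs / ik_phi
                row["raib_ratio_instant_kill"] = (
                    1.0 if ik_raib == 0.0 and rb == 0.0 else rb / ik_raib
                    if ik_raib != 0.0
                    else np.inf
                )
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DifferentialResult:
    """One malaria-differential biopesticide scenario."""

    intervention: Intervention
    initial_raib: float
    selection_coefficient: float
    trajectory: PMTrajectory
    time_to_failure: int | None


def differential_virulence_run(
    infected_sched: VirulenceSchedule,
    uninfected_rates: list[float],
    coverage: float,
    bio: BiologyParams,
    pop: PopulationParams,
    failure_threshold: float = 0.5,
) -> list[DifferentialResult]:
    """Population trajectories for biopesticides sharing one schedule in
    malaria-infected mosquitoes while the daily mortality for malaria-free
    mosquitoes varies (same initiation day)."""
    ref = _untreated(bio)
    out = []
    for rate in uninfected_rates:
        iv = Intervention.biopesticide(
            coverage,
            infected_sched.initiation_day,
            infected_sched.daily_mortality,
            uninfected_daily_mortality=rate,
        )
        fit = run_fcm(bio, iv)
        traj = run_pm(bio, iv, pop)
        out.append(
            DifferentialResult(
                intervention=iv,
                initial_raib=raib(fit, ref),
                selection_coefficient=selection_coefficient(fit, ref),
                trajectory=traj,
                time_to_failure=traj.time_to_failure(failure_threshold),
            )
        )
    return out
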