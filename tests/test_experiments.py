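import numpy as np
import pytest

from llasim import (
    Intervention,
    InfeasibleError,
    PopulationParams,
    VirulenceGrid,
    calibrate_matching_virulence,
    coverage_sweep,
    differential_virulence_run,
    iso_raib_curve,
    matched_control_set,
    min_selection_coefficient,
    raib,
    run_fcm,
    run_pm,
)
from llasim.interventions import VirulenceSchedule


@pytest.fixture(scope="module")
def curve_08(bio):
    return iso_raib_curve(0.90, VirulenceGrid(coverage=0.8), bio)


class TestIsoRaibCurve:
    def test_solutions_reproduce_target(self, bio, untreated_fcm, curve_08):
        for p in curve_08:
            achieved = raib(
                run_fcm(
                    bio, Intervention.biopesticide(0.8, p.initiation_day, p.daily_mortality)
                ),
                untreated_fcm,
            )
            assert achieved == pytest.approx(0.90, abs=1e-5)

    def test_required_mortality_rises_with_initiation_day(self, curve_08):
        rates = [p.daily_mortality for p in curve_08]
        assert all(b >= a - 1e-9 for a, b in zip(rates, rates[1:]))
        # immediate initiation needs the lowest rate on the curve
        assert rates[0] == min(rates)

    def test_unreachable_target_returns_empty(self, bio):
        assert iso_raib_curve(0.99, VirulenceGrid(coverage=0.5), bio) == []

    def test_curve_terminates_when_target_becomes_unreachable(self, curve_08):
        # later initiation days fall off the 90% curve at 80% coverage
        days = [p.initiation_day for p in curve_08]
        assert days == sorted(days)
        assert max(days) < 14


class TestMinSelectionCoefficient:
    def test_minimum_dominates_curve(self, bio, curve_08):
        best = min_selection_coefficient(0.90, 0.8, bio=bio)
        assert all(
            best.selection_coefficient <= p.selection_coefficient + 1e-12
            for p in curve_08
        )
        # the optimum sits at the latest feasible initiation day
        assert best.initiation_day == max(p.initiation_day for p in curve_08)

    def test_zero_coverage_infeasible(self, bio):
        with pytest.raises(InfeasibleError):
            min_selection_coefficient(0.90, 0.0, bio=bio)

    def test_high_target_low_coverage_infeasible(self, bio):
        with pytest.raises(InfeasibleError):
            min_selection_coefficient(0.99, 0.5, bio=bio)


class TestCalibrateMatchingVirulence:
    def test_zero_reference_gives_zero_mortality(self, bio):
        iv = calibrate_matching_virulence(Intervention.none(), 3, 0.8, bio)
        assert iv.virulence_infected.daily_mortality == 0.0

    def test_matches_instant_kill_raib(self, bio, untreated_fcm):
        reference = Intervention.instant_kill(0.3)
        matched = calibrate_matching_virulence(reference, 0, 0.3, bio)
        assert raib(run_fcm(bio, matched), untreated_fcm) == pytest.approx(
            raib(run_fcm(bio, reference), untreated_fcm), abs=1e-5
        )

    def test_matched_biopesticide_never_speeds_resistance(self, bio):
        """Matching instant-kill control at equal coverage forces total
        daily mortality from day 0, which removes contacted mosquitoes
        before they lay — so the matched biopesticide spreads resistance no
        faster than the chemical (and exactly as fast in the limiting
        case).  Any later-initiating schedule trades a little control for
        strictly slower evolution."""
        reference = Intervention.instant_kill(0.3)
        matched = calibrate_matching_virulence(reference, 0, 0.3, bio)
        pop = PopulationParams(n_periods=400)
        r_ik = run_pm(bio, reference, pop).resistant_fraction
        r_bp = run_pm(bio, matched, pop).resistant_fraction
        assert r_bp[-1] <= r_ik[-1] + 1e-12
        softer = Intervention.biopesticide(0.3, 3, 1.0)
        r_soft = run_pm(bio, softer, pop).resistant_fraction
        assert r_soft[-1] < r_ik[-1]

    def test_unreachable_reference_raises(self, bio):
        reference = Intervention.instant_kill(0.9)
        with pytest.raises(InfeasibleError):
            calibrate_matching_virulence(reference, 12, 0.2, bio)


@pytest.fixture(scope="module")
def templates():
    return [
        Intervention.instant_kill(1.0),
        Intervention.biopesticide(1.0, 3, 0.72),
        Intervention.biopesticide(1.0, 9, 0.91),
    ]


class TestCoverageSweep:
    def test_zero_coverage_row_is_neutral(self, bio, templates):
        frame = coverage_sweep(templates, [0.0], bio)
        assert np.allclose(frame["raib"], 0.0)
        assert np.allclose(frame["selection_coefficient"], 0.0)
        assert np.allclose(frame["lrs_ratio_instant_kill"], 1.0)
        assert np.allclose(frame["raib_ratio_instant_kill"], 1.0)

    def test_raib_monotone_in_coverage(self, bio, templates):
        frame = coverage_sweep(templates, [0.0, 0.25, 0.5, 0.75, 1.0], bio)
        for _, group in frame.groupby("intervention"):
            raibs = group.sort_values("coverage")["raib"].to_numpy()
            assert np.all(np.diff(raibs) >= -1e-12)

    def test_repellency_shifts_advantage_to_biopesticides(self, bio, templates):
        """With a contact-repellent comparator the biopesticides' relative
        EIR reduction improves at every coverage."""
        repellent = [Intervention.instant_kill(1.0, repellency=0.5)] + templates[1:]
        covs = [0.3, 0.6, 0.9]
        plain = coverage_sweep(templates, covs, bio)
        shifted = coverage_sweep(repellent, covs, bio)
        for key in ("biopesticide(day=3,rate=0.72)", "biopesticide(day=9,rate=0.91)"):
            a = plain[plain.intervention == key]["raib_ratio_instant_kill"].to_numpy()
            b = shifted[shifted.intervention == key]["raib_ratio_instant_kill"].to_numpy()
            assert np.all(b > a)


class TestMatchedControlSet:
    def test_common_initial_raib(self, bio, untreated_fcm):
        ivs = matched_control_set(bio, 0.90, 0.8, (0, 5, 9))
        assert ivs[0].kind == "instant_kill"
        for iv in ivs:
            assert raib(run_fcm(bio, iv), untreated_fcm) == pytest.approx(
                0.90, abs=1e-5
            )


class TestDifferentialVirulence:
    def test_uniform_rate_degenerates_to_standard_biopesticide(self, bio, pop):
        sched = VirulenceSchedule(3, 0.72)
        small_pop = PopulationParams(n_periods=30)
        res = differential_virulence_run(sched, [0.72], 0.8, bio, small_pop)[0]
        standard = run_pm(bio, Intervention.biopesticide(0.8, 3, 0.72), small_pop)
        assert np.allclose(
            res.trajectory.relative_bite_output, standard.relative_bite_output
        )

    def test_infected_only_mortality_minimizes_selection(self, bio):
        sched = VirulenceSchedule(3, 0.72)
        small_pop = PopulationParams(n_periods=120)
        results = differential_virulence_run(
            sched, [0.72, 0.25, 0.0], 0.8, bio, small_pop
        )
        scs = [r.selection_coefficient for r in results]
        assert scs[-1] == min(scs)
        final_R = [r.trajectory.resistant_fraction[-1] for r in results]
        assert final_R[-1] == min(final_R)
        # transmission control is preserved across the whole family
        for r in results:
            assert r.initial_raib > 0.95
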