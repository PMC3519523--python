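import math

import numpy as np
import pytest

from llasim import (
    BiologyParams,
    Intervention,
    MosquitoState,
    raib,
    run_fcm,
    selection_coefficient,
)
from llasim.fcm import UndefinedMetricError, cycle_transition


def untreated_cycle_survival(bio: BiologyParams) -> float:
    """Closed form: background survival over the three activity segments
    times both attack survivals (host choice does not alter survival absent
    treatment)."""
    active = bio.host_search_time + bio.resting_time + bio.oviposition_search_time
    return (
        math.exp(-bio.background_mortality_rate * active)
        * (1.0 - bio.pre_bite_attack_mortality)
        * (1.0 - bio.post_bite_attack_mortality)
    )


class TestCycleTransition:
    def test_untreated_expected_eggs_closed_form(self, bio):
        rec = cycle_transition(MosquitoState(1), bio, Intervention.none())
        expected = bio.eggs_per_laying * untreated_cycle_survival(bio)
        assert rec.eggs == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(64.64, abs=0.01)

    def test_probability_conservation(self, bio, scenario_interventions):
        for iv in scenario_interventions.values():
            for state in (MosquitoState(1), MosquitoState(5, 2, 1), MosquitoState(7, 4, 3)):
                rec = cycle_transition(state, bio, iv)
                assert rec.death_prob + sum(rec.outcomes.values()) == pytest.approx(
                    1.0, abs=1e-12
                )

    def test_resistance_neutral_without_treatment(self, bio):
        state = MosquitoState(3, 1, 0)
        a = cycle_transition(state, bio, Intervention.none(), resistant=False)
        b = cycle_transition(state, bio, Intervention.none(), resistant=True)
        assert a == b

    def test_instant_kill_full_coverage_kills_every_human_biter(self, bio):
        rec = cycle_transition(
            MosquitoState(1), bio, Intervention.instant_kill(1.0)
        )
        # only the non-human-host branch survives
        expected = bio.nonhuman_host_prob * untreated_cycle_survival(bio)
        assert rec.survival == pytest.approx(expected, rel=1e-12)

    def test_state_validation(self, bio):
        with pytest.raises(ValueError):
            MosquitoState(3, malaria_age=3)
        with pytest.raises(ValueError):
            MosquitoState(2, fungal_age=2)
        with pytest.raises(ValueError):
            cycle_transition(
                MosquitoState(bio.max_age_classes + 1), bio, Intervention.none()
            )


class TestRunFCM:
    def test_untreated_survival_is_age_independent(self, bio, untreated_fcm):
        V = untreated_fcm.alive_probs
        ratios = V[1:] / V[:-1]
        s = untreated_cycle_survival(bio)
        assert np.allclose(ratios, s, rtol=1e-12)
        assert np.allclose(untreated_fcm.cycle_survival, s, rtol=1e-12)

    @pytest.mark.parametrize(
        "key",
        [
            "none",
            "instant_kill",
            "instant_kill_repellent",
            "biopesticide_early",
            "biopesticide_late",
            "biopesticide_differential",
        ],
    )
    def test_state_mass_conservation(self, bio, scenario_interventions, key):
        res = run_fcm(bio, scenario_interventions[key])
        for i, states in enumerate(res.state_probs):
            assert sum(states.values()) == pytest.approx(
                res.alive_probs[i], abs=1e-12
            )
            assert all(m < i + 1 and l < i + 1 for (m, l) in states)
        assert np.all(
            np.abs(
                res.alive_probs[1:]
                - res.cycle_survival[:-1] * res.alive_probs[:-1]
            )
            < 1e-12
        )
        assert res.alive_probs[0] == 1.0

    def test_untreated_has_positive_infectious_output(self, untreated_fcm):
        assert untreated_fcm.lifetime_infectious_bites > 0
        assert untreated_fcm.lifetime_eggs > 0

    def test_resistant_equals_untreated_under_any_intervention(
        self, bio, untreated_fcm, scenario_interventions
    ):
        for iv in scenario_interventions.values():
            res = run_fcm(bio, iv, resistant=True)
            assert res.lifetime_eggs == pytest.approx(
                untreated_fcm.lifetime_eggs, rel=1e-12
            )
            assert res.lifetime_infectious_bites == pytest.approx(
                untreated_fcm.lifetime_infectious_bites, rel=1e-12
            )

    def test_bites_recorded_before_insecticide_kill(self, bio):
        # full-coverage instant kill still cannot yield infectious bites:
        # the malaria-acquiring bite itself is fatal, so no mosquito ever
        # carries a mature infection
        res = run_fcm(bio, Intervention.instant_kill(1.0))
        assert res.lifetime_infectious_bites == 0.0
        # at partial coverage the pre-kill bite accounting leaves u positive
        res = run_fcm(bio, Intervention.instant_kill(0.99))
        assert res.lifetime_infectious_bites > 0.0


class TestMetrics:
    def test_identity_cases(self, untreated_fcm):
        assert raib(untreated_fcm, untreated_fcm) == 0.0
        assert selection_coefficient(untreated_fcm, untreated_fcm) == 0.0

    def test_zero_coverage_neutrality(self, bio, untreated_fcm):
        for iv in (
            Intervention.none(),
            Intervention.instant_kill(0.0),
            Intervention.biopesticide(0.0, 3, 0.72),
        ):
            res = run_fcm(bio, iv)
            assert raib(res, untreated_fcm) == 0.0
            assert selection_coefficient(res, untreated_fcm) == 0.0

    def test_complete_control(self, bio, untreated_fcm):
        res = run_fcm(bio, Intervention.instant_kill(1.0))
        assert raib(res, untreated_fcm) == 1.0

    def test_undefined_metrics_raise(self, bio, untreated_fcm):
        dead = run_fcm(bio, Intervention.instant_kill(1.0))
        # a hypothetical reference with no infectious bites
        with pytest.raises(UndefinedMetricError):
            raib(untreated_fcm, dead)

    def test_immediate_total_virulence_between_untreated_and_instant_kill(
        self, bio, untreated_fcm
    ):
        """A biopesticide killing on contact day 0 at 100%/day acts like an
        instant-kill delayed to the oviposition flight: infected mosquitoes
        die before laying, so lifetime eggs and bites coincide with the
        instant-kill values at equal coverage."""
        bp = run_fcm(bio, Intervention.biopesticide(0.8, 0, 1.0))
        ik = run_fcm(bio, Intervention.instant_kill(0.8))
        assert ik.lifetime_eggs <= bp.lifetime_eggs < untreated_fcm.lifetime_eggs
        assert bp.lifetime_eggs == pytest.approx(ik.lifetime_eggs, rel=1e-12)
        assert bp.lifetime_infectious_bites == pytest.approx(
            ik.lifetime_infectious_bites, rel=1e-12
        )

    def test_differential_virulence_spares_fitness(self, bio, untreated_fcm):
        """Confining fungal mortality to malaria-infected mosquitoes keeps
        transmission control while nearly eliminating the fitness cost."""
        uniform = run_fcm(bio, Intervention.biopesticide(0.8, 3, 0.72))
        infected_only = run_fcm(
            bio, Intervention.biopesticide(0.8, 3, 0.72, uninfected_daily_mortality=0.0)
        )
        assert raib(infected_only, untreated_fcm) > 0.95
        assert (
            selection_coefficient(infected_only, untreated_fcm)
            < 0.2 * selection_coefficient(uniform, untreated_fcm)
        )
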