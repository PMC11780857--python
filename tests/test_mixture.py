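"""Permutation attribution vs its enumeration oracle; estimator sanity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from omt.cohort import sample_response
from omt.mixture import (
    attribute_trial,
    exact_attribution,
    participant_mixture,
)
from omt.task_design import make_session_schedule
from conftest import make_trial
from test_cohort import flat_params
from test_metrics import make_response


TARGET = (0.5, 0.5)
DISTRACTORS = [(0.9, 0.9)]


class TestAttributeTrial:
    def test_zero_distance_dominates(self):
        att = attribute_trial(
            TARGET, TARGET, DISTRACTORS, np.array([[0.5, 0.5], [0.1, 0.1]]),
            rng=np.random.default_rng(0),
        )
        assert att.p_target_hat == 1.0

    def test_no_misbinding_without_distractors(self):
        att = attribute_trial(
            (0.4, 0.4), TARGET, [], np.array([[0.1, 0.1], [0.4, 0.45]]),
            rng=np.random.default_rng(0),
        )
        assert att.p_misbind_hat == 0.0
        assert att.d_nearest_distractor is None

    def test_fixed_geometry_matches_enumeration(self):
        """Permutation estimate within 3 binomial SEs of the pool enumeration."""
        response, target = (0.85, 0.85), (0.5, 0.5)
        pool = np.array([[0.1, 0.1], [0.84, 0.84]])
        exact = exact_attribution(response, target, DISTRACTORS, pool)
        # pool point (0.84, 0.84) is strictly nearer than target and distractor
        assert exact.p_guess_hat == pytest.approx(0.5)
        att = attribute_trial(
            response, target, DISTRACTORS, pool, n_reps=5000,
            rng=np.random.default_rng(1),
        )
        se = np.sqrt(0.5 * 0.5 / 5000)
        for field in ("p_target_hat", "p_misbind_hat", "p_guess_hat"):
            assert abs(getattr(att, field) - getattr(exact, field)) < 3 * se

    def test_tie_breaks_follow_fixed_priority(self):
        # dyadic coordinates make the distances exactly equal in floats
        # distractor tied with pool draw -> misbinding wins
        att = exact_attribution(
            (0.75, 0.75), (0.25, 0.25), [(0.875, 0.875)],
            np.array([[0.625, 0.625]]),
        )
        assert att.p_misbind_hat == 1.0
        # target tied with distractor -> target wins
        att = exact_attribution(
            (0.75, 0.75), (0.625, 0.625), [(0.875, 0.875)],
            np.array([[0.1, 0.1]]),
        )
        assert att.p_target_hat == 1.0

    def test_pool_of_one_equals_exact(self):
        pool = np.array([[0.3, 0.7]])
        exact = exact_attribution((0.4, 0.4), TARGET, DISTRACTORS, pool)
        for reps in (1, 7, 500):
            att = attribute_trial(
                (0.4, 0.4), TARGET, DISTRACTORS, pool, n_reps=reps,
                rng=np.random.default_rng(2),
            )
            assert (att.p_target_hat, att.p_misbind_hat, att.p_guess_hat) == (
                exact.p_target_hat, exact.p_misbind_hat, exact.p_guess_hat
            )

    def test_input_validation(self):
        with pytest.raises(ValueError):
            attribute_trial(TARGET, TARGET, [], np.empty((0, 2)))
        with pytest.raises(ValueError):
            attribute_trial(TARGET, TARGET, [], np.array([[0.1, 0.1]]), n_reps=0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_normalization_is_exact_for_random_geometries(self, seed):
        rng = np.random.default_rng(seed)
        response, target = rng.uniform(0, 1, 2), rng.uniform(0, 1, 2)
        distractors = [tuple(rng.uniform(0, 1, 2)) for _ in range(rng.integers(0, 3))]
        pool = rng.uniform(0, 1, (int(rng.integers(1, 40)), 2))
        for att in (
            exact_attribution(tuple(response), tuple(target), distractors, pool),
            attribute_trial(
                tuple(response), tuple(target), distractors, pool, n_reps=777, rng=rng
            ),
        ):
            assert (att.p_target_hat + att.p_misbind_hat) + att.p_guess_hat == 1.0
            assert 0.0 <= att.p_target_hat <= 1.0
            assert 0.0 <= att.p_misbind_hat <= 1.0


class TestParticipantMixture:
    def test_perfect_responses(self):
        trials = []
        for i, loc in enumerate(((0.2, 0.2), (0.5, 0.8), (0.8, 0.3), (0.3, 0.6))):
            t = make_trial(set_size=1, locs=(loc,), trial_id=i)
            trials.append((t, make_response(loc)))
        est = participant_mixture(trials, rng=np.random.default_rng(0))
        assert est.target_detection == 1.0
        assert est.guessing == 0.0
        assert est.imprecision == 0.0

    def test_misbinding_zero_for_one_item_conditions(self, ehc_participant_trials):
        est = participant_mixture(
            ehc_participant_trials, rng=np.random.default_rng(1)
        )
        for (ss, _), vals in est.by_condition.items():
            if ss == 1:
                assert np.isnan(vals["misbinding"])
            else:
                assert 0.0 <= vals["misbinding"] <= 1.0

    def test_condition_proportions_sum_to_one(self, ehc_participant_trials):
        est = participant_mixture(
            ehc_participant_trials, rng=np.random.default_rng(2), exact=True
        )
        for (ss, _), vals in est.by_condition.items():
            total = vals["target_detection"] + vals["guessing"]
            if ss == 3:
                total += vals["misbinding"]
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_seeded_determinism(self, ehc_participant_trials):
        a = participant_mixture(ehc_participant_trials, rng=np.random.default_rng(3))
        b = participant_mixture(ehc_participant_trials, rng=np.random.default_rng(3))
        assert (a.target_detection, a.misbinding, a.guessing, a.imprecision) == (
            b.target_detection, b.misbinding, b.guessing, b.imprecision
        )
        for cond in a.by_condition:
            np.testing.assert_array_equal(
                list(a.by_condition[cond].values()),
                list(b.by_condition[cond].values()),
            )

    def test_no_correct_trials_missing(self):
        t = make_trial(set_size=1, locs=((0.5, 0.5),))
        trials = [(t, make_response(identified=False))] * 5
        with pytest.warns(UserWarning):
            assert participant_mixture(trials, rng=np.random.default_rng(0)) is None

    def test_misbinding_monotone_in_generative_weight(self):
        """More generative swap mass -> higher estimated misbinding."""
        rng = np.random.default_rng(4)
        est = {}
        for name, (pt, pm, pg) in {
            "none": (0.85, 0.0, 0.15), "some": (0.7, 0.15, 0.15)
        }.items():
            params = flat_params(pt, pm, pg, 0.04)
            _, test = make_session_schedule(
                rng.integers(2**31), blocks=6
            )
            trials = [(t, sample_response(t, params, rng)) for t in test]
            est[name] = participant_mixture(trials, rng=rng, exact=True).misbinding
        assert est["some"] > est["none"]

    def test_exact_and_permutation_agree_on_participant(self, ehc_participant_trials):
        a = participant_mixture(
            ehc_participant_trials, rng=np.random.default_rng(5), exact=True
        )
        b = participant_mixture(
            ehc_participant_trials, n_reps=5000, rng=np.random.default_rng(5)
        )
        assert a.target_detection == pytest.approx(b.target_detection, abs=0.02)
        assert a.misbinding == pytest.approx(b.misbinding, abs=0.02)
        assert a.guessing == pytest.approx(b.guessing, abs=0.02)
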