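"""Inferential procedures: hand-computed oracles and algebraic identities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from omt.stats import (
    ancova_groups,
    classify_eta_squared,
    compare_dependent_overlapping_correlations,
    factorial_2x2,
    glm_hv,
    holm_adjust,
    longitudinal_ancova,
    predict_decline,
)


def random_covariates(rng, n):
    return pd.DataFrame(
        {
            "age": rng.normal(68, 7, n),
            "gender": rng.integers(0, 2, n).astype(float),
            "education": rng.normal(14, 3, n),
        }
    )


class TestHolm:
    def test_hand_computed_step_down(self):
        np.testing.assert_allclose(
            holm_adjust([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06]
        )

    def test_single_p_unchanged(self):
        assert holm_adjust([0.2])[0] == pytest.approx(0.2)

    def test_smallest_is_bonferroni(self):
        p = [0.003, 0.2, 0.9, 0.04]
        assert min(holm_adjust(p)) == pytest.approx(4 * 0.003)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    def test_matches_direct_step_down_formula(self, pvals):
        """Independent transcription of the step-down definition."""
        m = len(pvals)
        order = np.argsort(pvals)
        expected = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * pvals[idx])
            expected[idx] = min(running, 1.0)
        np.testing.assert_allclose(holm_adjust(pvals), expected, atol=1e-12)
        adjusted = holm_adjust(pvals)
        assert np.all(adjusted >= np.asarray(pvals) - 1e-15)
        assert np.all(adjusted <= 1.0)


class TestAncova:
    def test_two_groups_f_equals_squared_t(self):
        rng = np.random.default_rng(0)
        n = 60
        group = np.repeat(["A", "B"], n // 2)
        metric = rng.normal(0, 1, n) + (group == "B") * 0.4
        res = ancova_groups(metric, group, random_covariates(rng, n))
        (contrast,) = res.pairwise
        assert res.F == pytest.approx(contrast.t**2, abs=1e-8)

    def test_designed_separation_detected(self):
        """EHC-vs-AD-like shift of 1.5 pooled SDs is found at n=50/group."""
        rng = np.random.default_rng(1)
        n = 100
        group = np.repeat(["EHC", "AD"], n // 2)
        metric = rng.normal(0, 1, n) - (group == "AD") * 1.5
        res = ancova_groups(metric, group, random_covariates(rng, n))
        assert res.p < 0.05
        assert res.eta_squared > 0.14

    def test_pairwise_table_shape_and_holm_domination(self):
        rng = np.random.default_rng(2)
        n = 80
        group = np.repeat(["EHC", "SCD", "MCI", "AD"], n // 4)
        metric = rng.normal(0, 1, n)
        res = ancova_groups(metric, group, random_covariates(rng, n))
        assert len(res.pairwise) == 6
        for c in res.pairwise:
            assert c.p_holm >= c.p_raw - 1e-15

    def test_rank_deficient_design_reported(self):
        rng = np.random.default_rng(3)
        n = 40
        cov = random_covariates(rng, n)
        cov["education"] = cov["age"] * 2.0  # collinear
        with pytest.raises(ValueError, match="rank-deficient"):
            ancova_groups(
                rng.normal(size=n), np.repeat(["A", "B"], n // 2), cov
            )

    def test_single_group_rejected(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError):
            ancova_groups(rng.normal(size=10), ["A"] * 10, random_covariates(rng, 10))


class TestFactorial:
    @staticmethod
    def _long(values, n):
        rows = []
        for pid in range(n):
            for (ss, dl) in ((1, 1.0), (1, 4.0), (3, 1.0), (3, 4.0)):
                rows.append(
                    {
                        "participant_id": pid,
                        "set_size": ss,
                        "delay_s": dl,
                        "value": values(pid, ss, dl),
                    }
                )
        return pd.DataFrame(rows)

    def test_planted_set_size_effect_only(self):
        rng = np.random.default_rng(0)
        df = self._long(
            lambda pid, ss, dl: rng.normal() + 0.8 * (ss == 3), n=100
        )
        effects = {e.effect_name: e for e in factorial_2x2(df)}
        assert effects["set_size"].p < 0.001
        assert effects["delay"].p > 0.05
        assert effects["set_size"].magnitude_class in ("medium", "large")

    def test_delay_only_analysis_for_three_item_metric(self):
        rng = np.random.default_rng(1)
        df = self._long(lambda pid, ss, dl: rng.normal() + 0.5 * (dl == 4.0), n=60)
        effects = factorial_2x2(df[df["set_size"] == 3])
        assert [e.effect_name for e in effects] == ["delay"]
        assert effects[0].p < 0.01

    def test_incomplete_participants_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        df = self._long(lambda pid, ss, dl: rng.normal(), n=20)
        df = df.drop(df[(df.participant_id == 0) & (df.set_size == 1)].index)
        with pytest.warns(UserWarning, match="missing cells"):
            factorial_2x2(df)

    @pytest.mark.parametrize(
        "eta2,label",
        [(0.005, "negligible"), (0.03, "small"), (0.10, "medium"), (0.20, "large")],
    )
    def test_eta_squared_magnitude_classes(self, eta2, label):
        assert classify_eta_squared(eta2) == label


class TestLongitudinal:
    @staticmethod
    def _frame(rng, n_per_group=15, session_shift=0.0, ad_shift=0.0):
        rows = []
        pid = 0
        for g in ("EHC", "SCD", "MCI", "AD"):
            for _ in range(n_per_group):
                base = rng.normal()
                age, gender, edu = rng.normal(68, 7), float(rng.integers(2)), rng.normal(14, 3)
                for session in (1, 2):
                    shift = session_shift if session == 2 else 0.0
                    if session == 2 and g == "AD":
                        shift += ad_shift
                    rows.append(
                        {
                            "participant_id": f"p{pid}",
                            "group": g,
                            "session": session,
                            "age": age,
                            "gender": gender,
                            "education": edu,
                            "metric": base + shift + rng.normal(0, 0.3),
                        }
                    )
                pid += 1
        return pd.DataFrame(rows)

    def test_constant_session_shift_gives_session_main_effect_only(self):
        rng = np.random.default_rng(0)
        df = self._frame(rng, session_shift=1.0)
        res = longitudinal_ancova(df, "metric")
        terms = {t.effect_name: t.p for t in res.terms}
        assert terms["session"] < 1e-6
        assert terms["interaction"] > 0.05

    def test_ad_only_shift_gives_interaction_and_ad_posthoc(self):
        rng = np.random.default_rng(1)
        df = self._frame(rng, ad_shift=1.0)
        res = longitudinal_ancova(df, "metric")
        terms = {t.effect_name: t.p for t in res.terms}
        assert terms["interaction"] < 0.01
        posthoc = {g: p for g, _, p in res.posthoc}
        assert posthoc["AD"] < 0.05

    def test_single_session_rejected(self):
        rng = np.random.default_rng(2)
        df = self._frame(rng)
        with pytest.raises(ValueError, match="two sessions"):
            longitudinal_ancova(df[df.session == 1], "metric")


class TestDecline:
    def test_exact_linear_relation(self):
        x = np.linspace(0, 1, 30)
        res = predict_decline(x, np.full(30, 90.0), 90.0 - 5 * x)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(-5.0)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            predict_decline([0.1, 0.2], [90, 91], [89, 90])


class TestDependentCorrelations:
    def test_equal_correlations_give_zero(self):
        res = compare_dependent_overlapping_correlations(0.5, 0.5, 0.3, 100)
        assert res.z == 0.0
        assert res.p == pytest.approx(1.0)

    @pytest.mark.parametrize("method", ["hittner_h", "steiger_z"])
    def test_matches_published_formula_transcription(self, method):
        """Cross-check against an independent transcription of the
        Fisher-z statistic for overlapping dependent correlations."""
        r_jk, r_jh, r_kh, n = 0.6, 0.3, 0.4, 138
        res = compare_dependent_overlapping_correlations(r_jk, r_jh, r_kh, n, method)

        z1, z2 = np.arctanh(r_jk), np.arctanh(r_jh)
        if method == "steiger_z":
            rm = (r_jk + r_jh) / 2
        else:
            rm = np.tanh((z1 + z2) / 2)
        num = r_kh * (1 - rm**2 - rm**2) - 0.5 * rm**2 * (
            1 - rm**2 - rm**2 - r_kh**2
        )
        cov = num / (1 - rm**2) ** 2
        expected = (z1 - z2) * np.sqrt((n - 3) / (2 - 2 * cov))
        assert res.z == pytest.approx(expected, abs=1e-6)
        assert res.z > 2.0  # clearly discrepant correlations at n=138

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            compare_dependent_overlapping_correlations(1.0, 0.3, 0.2, 50)
        with pytest.raises(ValueError):
            compare_dependent_overlapping_correlations(0.5, 0.3, 0.2, 3)
        with pytest.raises(ValueError):
            compare_dependent_overlapping_correlations(0.5, 0.3, 0.2, 50, "other")


class TestHVRegression:
    def test_perfect_predictor(self):
        rng = np.random.default_rng(0)
        n = 50
        hv = rng.normal(7000, 600, n)
        res = glm_hv(hv, hv, random_covariates(rng, n))
        assert res.r_squared_model == pytest.approx(1.0)
        assert res.p < 1e-20

    def test_permuted_predictor_is_null(self):
        """Permutation null: rejection rate stays near alpha."""
        rng = np.random.default_rng(1)
        n = 60
        hv = rng.normal(7000, 600, n)
        metric = 0.5 * (hv - 7000) / 600 + rng.normal(0, 1, n)
        cov = random_covariates(rng, n)
        rejections = 0
        n_perm = 200
        for _ in range(n_perm):
            res = glm_hv(hv, rng.permutation(metric), cov)
            rejections += res.p < 0.05
        assert 0.0 <= rejections / n_perm < 0.12
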