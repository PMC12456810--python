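"""Statistical contracts: FDR, effect sizes, GLM families, mixed model."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import rhythmdm as r
from rhythmdm import stats
from rhythmdm.stats import ModelSpecificationError


class TestBHFDR:
    def test_hand_worked_stepup(self):
        adj = r.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert r.bh_fdr([0.3]) == pytest.approx([0.3])

    def test_all_ones(self):
        assert np.allclose(r.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            r.bh_fdr([0.5, 1.5])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_order_invariant_rank_preserving_and_dominating(self, ps):
        adj = r.bh_fdr(ps)
        assert (adj >= np.asarray(ps) - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()
        perm = np.random.default_rng(0).permutation(len(ps))
        adj_perm = r.bh_fdr(np.asarray(ps)[perm])
        # permuting the inputs permutes the outputs identically
        assert np.allclose(adj[perm], adj_perm)
        # the step-up adjustment never reorders the evidence
        order = np.argsort(ps, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestEffectSizes:
    def test_identical_composition_zero(self):
        inc = pd.DataFrame({"g": ["a"] * 10 + ["b"] * 10})
        exc = pd.DataFrame({"g": ["a"] * 5 + ["b"] * 5})
        out = r.attrition_effect_sizes(inc, exc, categorical=["g"])
        assert out.loc[0, "effect_size"] == pytest.approx(0.0, abs=1e-12)
        assert not out.loc[0, "flagged"]

    def test_perfect_separation_is_one(self):
        inc = pd.DataFrame({"g": ["a"] * 10})
        exc = pd.DataFrame({"g": ["b"] * 10})
        out = r.attrition_effect_sizes(inc, exc, categorical=["g"])
        assert out.loc[0, "effect_size"] == pytest.approx(1.0)
        assert out.loc[0, "flagged"]

    def test_worked_two_by_two(self):
        # inclusion x category (20,10 / 10,20): chi2 = 20/3, V = 1/3
        x = ["a"] * 20 + ["b"] * 10 + ["a"] * 10 + ["b"] * 20
        incl = [1] * 30 + [0] * 30
        assert r.cramers_v(x, incl) == pytest.approx(1 / 3)

    def test_constant_variable_reported_as_undefined(self):
        inc = pd.DataFrame({"g": ["a"] * 5, "age": [30] * 5})
        exc = pd.DataFrame({"g": ["a"] * 5, "age": [30] * 5})
        out = r.attrition_effect_sizes(
            inc, exc, categorical=["g"], continuous=["age"]
        )
        assert out["note"].str.contains("constant").all()
        assert out["effect_size"].isna().all()

    def test_spearman_for_continuous(self):
        inc = pd.DataFrame({"age": np.arange(30, 50)})
        exc = pd.DataFrame({"age": np.arange(20, 30)})
        out = r.attrition_effect_sizes(inc, exc, categorical=[], continuous=["age"])
        assert out.loc[0, "effect_size"] > 0.5
        assert out.loc[0, "flagged"]


def _marker_fixture(n=120, seed=0):
    """RDM-like table + covariates + null outcomes for GLM contracts."""
    rng = np.random.default_rng(seed)
    pids = [f"s{i:03d}" for i in range(n)]
    tab = pd.DataFrame({"participant_id": pids, "group": "schizophrenia"})
    for m in stats.MARKER_COLUMNS:
        tab[m] = rng.gamma(5, 2, n)
    tab["mean_self_symptoms"] = rng.uniform(6, 20, n)
    cov = pd.DataFrame(
        {
            "participant_id": pids,
            "site": rng.choice(["UTD", "Miami", "UCSD"], n),
            "age": rng.integers(18, 66, n),
            "gender": rng.choice(["Men", "Women"], n),
            "ethnoracial": rng.choice(["Asian", "Black", "White"], n),
            "education": rng.choice(["HS", "College"], n),
        }
    )
    scores = pd.DataFrame(
        {
            "participant_id": pids,
            "positive_symptoms": rng.gamma(8, 2, n) + 7,
            "emotional_experience": rng.gamma(6, 1, n) + 3,
            "emotional_expression": rng.gamma(6, 1, n) + 4,
        }
    )
    return tab, cov, scores


class TestMarkerAssociationModels:
    def test_noise_free_self_association_is_significant(self):
        tab, cov, scores = _marker_fixture(seed=1)
        scores = scores.copy()
        scores["positive_symptoms"] = tab["MH"] + 7.0  # marker leaks into outcome
        results = r.fit_rdm_symptom_models(tab, scores, cov)
        hit = [
            x
            for x in results
            if x.outcome == "positive_symptoms" and x.predictor == "MH"
        ][0]
        assert hit.p_value < 1e-6
        assert hit.p_adjusted < 0.05
        assert hit.scale == "log" and hit.mean_ratio > 1.0

    def test_family_size_and_fdr_monotonicity(self):
        tab, cov, scores = _marker_fixture(seed=2)
        results = r.fit_rdm_symptom_models(tab, scores, cov)
        assert len(results) == 3 * len(stats.MARKER_COLUMNS)
        for x in results:
            assert x.p_adjusted >= x.p_value - 1e-12
            assert x.conf_low <= x.estimate <= x.conf_high

    def test_missing_covariate_column_is_named(self):
        tab, cov, scores = _marker_fixture(seed=3)
        with pytest.raises(ModelSpecificationError, match="site"):
            r.fit_rdm_symptom_models(tab, scores, cov.drop(columns=["site"]))

    def test_rank_deficiency_rejected(self):
        tab, cov, scores = _marker_fixture(n=6, seed=4)
        with pytest.raises(ModelSpecificationError):
            r.fit_rdm_symptom_models(tab.head(6), scores.head(6), cov.head(6))

    def test_nonpositive_outcome_rejected(self):
        tab, cov, scores = _marker_fixture(seed=5)
        scores.loc[0, "positive_symptoms"] = 0.0
        with pytest.raises(ModelSpecificationError, match="strictly positive"):
            r.fit_rdm_symptom_models(tab, scores, cov)


class TestGroupDifferences:
    def _two_group_tables(self, seed, shift=0.0):
        rng = np.random.default_rng(seed)
        n = 60
        pids = [f"p{i:03d}" for i in range(2 * n)]
        tab = pd.DataFrame(
            {"participant_id": pids, "group": ["control"] * n + ["schizophrenia"] * n}
        )
        for m in stats.MARKER_COLUMNS:
            tab[m] = rng.normal(10, 2, 2 * n)
        tab.loc[tab.group == "schizophrenia", "MEHT_UU"] += shift
        tab["mean_self_symptoms"] = rng.uniform(6, 20, 2 * n)
        cov = pd.DataFrame(
            {
                "participant_id": pids,
                "site": rng.choice(["UTD", "Miami"], 2 * n),
                "age": rng.integers(18, 66, 2 * n),
                "gender": rng.choice(["Men", "Women"], 2 * n),
                "ethnoracial": rng.choice(["Black", "White"], 2 * n),
                "education": rng.choice(["HS", "College"], 2 * n),
            }
        )
        return tab, cov

    def test_null_groups_cover_zero(self):
        tab, cov = self._two_group_tables(seed=0)
        results = r.fit_group_differences(tab, cov)
        cover = [x.conf_low <= 0 <= x.conf_high for x in results]
        assert np.mean(cover) >= 0.8  # nominal 95% coverage, small family
        assert not any(x.significant for x in results)

    def test_injected_shift_detected_with_right_sign(self):
        tab, cov = self._two_group_tables(seed=1, shift=4.0)
        results = r.fit_group_differences(tab, cov)
        hit = [x for x in results if x.outcome == "MEHT_UU"][0]
        assert hit.estimate > 0
        assert hit.p_adjusted < 0.05

    def test_contrast_coding_references(self, fitted_small, small_cohort):
        _, _, trajectories = small_cohort
        cov = r.generate_covariates(trajectories, seed=5)
        cov = cov.merge(
            fitted_small.rdm_table[["participant_id", "mean_self_symptoms"]],
            on="participant_id",
        )
        results = fitted_small.group_differences(cov)
        contrasts = {x.predictor for x in results}
        assert contrasts == {
            "bipolar_vs_control",
            "schizophrenia_vs_control",
            "schizophrenia_vs_bipolar",
        }

    def test_single_group_rejected(self):
        tab, cov = self._two_group_tables(seed=2)
        solo = tab[tab.group == "control"]
        with pytest.raises(ModelSpecificationError):
            r.fit_group_differences(solo, cov)


class TestOrthogonalCovariates:
    def test_orthogonal_covariates_leave_marker_coefficient_unchanged(self):
        # mirrored design: every covariate pattern appears once per group
        rng = np.random.default_rng(7)
        half = pd.DataFrame(
            {
                "site": ["UTD", "Miami"] * 8,
                "gender": (["Men"] * 2 + ["Women"] * 2) * 4,
                "ethnoracial": ["Black"] * 8 + ["White"] * 8,
                "education": (["HS"] * 4 + ["College"] * 4) * 2,
                "age": rng.permutation(np.arange(20, 52, 2)),
                "mean_self_symptoms": np.round(rng.uniform(8, 20, 16), 2),
            }
        )
        df = pd.concat(
            [half.assign(group="control"), half.assign(group="schizophrenia")],
            ignore_index=True,
        )
        df["participant_id"] = [f"p{i}" for i in range(len(df))]
        for m in stats.MARKER_COLUMNS:
            df[m] = rng.normal(10, 2, len(df))
        cov_cols = ["participant_id"] + list(stats.COVARIATE_COLUMNS)
        adj = r.fit_group_differences(df, df[cov_cols], adjusted=True)
        raw = r.fit_group_differences(df, df[cov_cols], adjusted=False)
        for a, b in zip(adj, raw):
            assert a.outcome == b.outcome and a.predictor == b.predictor
            assert a.estimate == pytest.approx(b.estimate, abs=1e-8)


class TestWithinBetweenMixedModel:
    def test_null_cohort_mean_ratios_cover_one(self, fitted_small):
        between, within, meta = fitted_small.within_between()
        for res in (between, within):
            lo, hi = res.ratio_ci
            assert lo <= 1.0 <= hi
            assert res.scale == "log"
            assert 0.5 < res.mean_ratio < 2.0
        assert meta["n_participants"] == len(fitted_small.participants)
        assert meta["backend"] in ("lme4", "glmmTMB")

    def test_degenerate_centered_predictor_flagged(self):
        df = pd.DataFrame(
            {
                "participant_id": ["a"] * 3 + ["b"] * 3,
                "SC": [10.0, 11.0, 9.0, 12.0, 13.0, 11.0],
                "person_mean_H": [1.0] * 3 + [2.0] * 3,
                "centered_H": [0.0] * 6,
            }
        )
        with pytest.raises(ModelSpecificationError, match="degenerate"):
            r.fit_within_between_model(df)

    def test_nonpositive_outcome_rejected(self):
        df = pd.DataFrame(
            {
                "participant_id": ["a", "a", "b"],
                "SC": [0.0, 10.0, 11.0],
                "person_mean_H": [1.0, 1.0, 2.0],
                "centered_H": [-0.1, 0.1, 0.0],
            }
        )
        with pytest.raises(ModelSpecificationError, match="strictly positive"):
            r.fit_within_between_model(df)
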