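from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuroentropy import (
    EntropyParams,
    MODEL_SPECS,
    MSEProfile,
    MixedEffectsModel,
    bh_fdr,
    build_long_table,
    fit_lme,
    gen_lme_dataset,
)

from _oracles import bh_oracle


def _profiles(n_subjects: int, rng: np.random.Generator, lobe: str = "frontal"):
    groups = ["non-user", "low-frequency", "frequent"]
    profs, meta = [], []
    for i in range(n_subjects):
        sid = f"S{i:03d}"
        profs.append(MSEProfile(sid, lobe, rng.uniform(1, 2, 20), EntropyParams()))
        meta.append({"subject_id": sid, "group": groups[i % 3],
                     "SPQTotal": int(rng.integers(5, 50)),
                     "AgeFirstUse": 18.0 if i % 3 else np.nan})
    return profs, pd.DataFrame(meta)


class TestBhFdr:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.05]), [0.05])

    def test_hand_computed_example(self):
        np.testing.assert_allclose(bh_fdr([0.005, 0.05, 0.5]), [0.015, 0.075, 0.5])

    def test_equal_spacing_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_matches_bruteforce_oracle_on_many_random_vectors(self, rng):
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 12))
            np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=10))
    def test_monotone_in_p(self, pvals):
        q = bh_fdr(pvals)
        order = np.argsort(pvals)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestBuildLongTable:
    def test_binned_cardinality(self, rng):
        profs, meta = _profiles(57, rng)
        table = build_long_table(profs, meta)
        assert len(table) == 57 * 4

    def test_bin_mean_of_known_values(self, rng):
        profs, meta = _profiles(1, rng)
        profs[0].entropy_by_scale = np.arange(1.0, 21.0)
        table = build_long_table(profs, meta)
        assert table.loc[table.scale_bin == "fine", "entropy"].iloc[0] == 3.0
        assert table.loc[table.scale_bin == "very-coarse", "entropy"].iloc[0] == 18.0

    def test_per_scale_mode(self, rng):
        profs, meta = _profiles(3, rng)
        table = build_long_table(profs, meta, mode="per-scale")
        assert len(table) == 3 * 20
        assert set(table["scale"]) == set(range(1, 21))

    def test_undefined_scales_excluded_from_bin_mean(self, rng):
        profs, meta = _profiles(1, rng)
        vals = np.arange(1.0, 21.0)
        vals[[0, 1]] = np.nan
        profs[0].entropy_by_scale = vals
        table = build_long_table(profs, meta)
        assert table.loc[table.scale_bin == "fine", "entropy"].iloc[0] == 4.0

    def test_users_only_subset_retains_39_of_57(self, rng):
        # study allocation: 18 non-users + 24 low-frequency + 15 frequent
        from neuroentropy.synthetic import STUDY_ALLOCATION

        groups = [g for g, n in STUDY_ALLOCATION.items() for _ in range(n)]
        profs, meta = _profiles(57, rng)
        meta["group"] = groups
        table = build_long_table(profs, meta)
        users = MODEL_SPECS["1B"].apply_subset(table)
        assert users.subject_id.nunique() == 39

    def test_missing_metadata_raises(self, rng):
        profs, meta = _profiles(4, rng)
        with pytest.raises(ValueError, match="missing"):
            build_long_table(profs, meta.iloc[:2])


class TestMixedEffectsModel:
    def test_balanced_fixed_effects_equal_ols(self):
        df = gen_lme_dataset(n_subjects=30, beta_interaction=0.3, icc=0.4, seed=1)
        res = MixedEffectsModel.from_formula(
            "response ~ C(group, Treatment('non-user')) * bin_index", df
        ).fit()
        import statsmodels.formula.api as smf

        ols = smf.ols(
            "response ~ C(group, Treatment('non-user')) * bin_index", df
        ).fit()
        np.testing.assert_allclose(
            res.fixed_effects["estimate"], ols.params.values, atol=1e-6
        )

    def test_parameter_recovery_of_interaction_slope(self):
        ests = []
        for s in range(50):
            df = gen_lme_dataset(n_subjects=120, beta_interaction=0.5, icc=0.5, seed=s)
            res = MixedEffectsModel.from_formula(
                "response ~ C(group, Treatment('non-user')) * bin_index", df
            ).fit()
            ests.append(
                res.fixed_effects.loc[
                    "C(group, Treatment('non-user'))[T.frequent]:bin_index", "estimate"
                ]
            )
        assert np.mean(ests) == pytest.approx(0.5, abs=0.05)

    def test_variance_components_recovered(self):
        df = gen_lme_dataset(n_subjects=400, beta_interaction=0.0, icc=0.5, seed=11)
        res = MixedEffectsModel.from_formula("response ~ bin_index", df).fit()
        assert res.random_intercept_var == pytest.approx(0.5, abs=0.06)
        assert res.residual_var == pytest.approx(0.5, abs=0.03)
        assert res.icc == pytest.approx(0.5, abs=0.05)

    def test_singular_design_names_collinear_terms(self):
        df = gen_lme_dataset(n_subjects=12, seed=0)
        df["dup"] = df["bin_index"]
        with pytest.raises(ValueError, match="collinear.*dup"):
            MixedEffectsModel.from_formula("response ~ bin_index + dup", df)

    def test_subject_with_single_observation_rejected(self):
        df = gen_lme_dataset(n_subjects=6, seed=0)
        df = pd.concat(
            [df, pd.DataFrame([{"subject_id": "LONER", "group": "non-user",
                                "scale_bin": "fine", "bin_index": 0,
                                "response": 1.0}])],
            ignore_index=True,
        )
        with pytest.raises(ValueError, match="LONER"):
            MixedEffectsModel.from_formula("response ~ bin_index", df)

    def test_wald_z_is_estimate_over_se(self, rng):
        df = gen_lme_dataset(n_subjects=30, seed=3)
        res = MixedEffectsModel.from_formula("response ~ bin_index", df).fit()
        fe = res.fixed_effects
        np.testing.assert_allclose(fe["z"], fe["estimate"] / fe["se"])


class TestStudyModels:
    def test_model_1a_fits_and_reports_interaction_terms(self, rng):
        profs, meta = _profiles(57, rng)
        res = fit_lme(build_long_table(profs, meta), "1A")
        fe = res.fixed_effects
        inter = [t for t in fe.index if "T.frequent]" in t and "scale_bin" in t]
        assert len(inter) == 3  # medium, coarse, very-coarse vs fine

    def test_posthoc_family_q_not_below_p(self, rng):
        profs, meta = _profiles(57, rng)
        res = fit_lme(build_long_table(profs, meta), "1A")
        sub = res.posthoc_contrasts("group_x_bin")
        assert len(sub) == 6  # 2 user groups × 3 non-reference bins
        assert (sub["q"] >= sub["p"] - 1e-12).all()

    def test_posthoc_single_contrast_q_equals_p(self, rng):
        profs, meta = _profiles(30, rng)
        res = fit_lme(build_long_table(profs, meta), "1A")
        term = res.fixed_effects.index[1]
        sub = res.posthoc_contrasts([term])
        assert sub["q"].iloc[0] == pytest.approx(sub["p"].iloc[0])

    def test_tidy_carries_families_and_summary_renders(self, rng):
        profs, meta = _profiles(30, rng)
        res = fit_lme(build_long_table(profs, meta), "1A")
        tidy = res.tidy()
        assert {"term", "estimate", "se", "z", "p", "q", "family"} <= set(tidy.columns)
        assert (tidy["family"] == "group_x_bin").sum() == 6
        assert "Mixed Linear Model" in str(res.summary())
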