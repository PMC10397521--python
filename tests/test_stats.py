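"""Per-subject regression, Bonferroni rule, group model, overlap, covariates."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import lesioncbf as lc
from lesioncbf.core_io import Mask, Volume
from lesioncbf.stats import (
    FACTOR_TERMS,
    SubjectRecord,
    bonferroni_assess,
    cbf_by_score,
    fit_factor_model,
    fit_score_regression,
    group_overlap_mask,
    paired_tissue_test,
    voxelwise_covariate_removal,
)
from lesioncbf.tigr import TIGR_SCORES, NormalizationBounds, TigrMap, tigr_score


def tigr_from_scores(score_data, affine=None):
    affine = np.eye(4) if affine is None else affine
    scores = np.asarray(score_data, float)
    lesion = Mask(scores > 0, affine, "lesion")
    return TigrMap(Volume(scores, affine), lesion)


def rows_from_line(intercept=42.0, slope=-20.0, noise=None, scores=TIGR_SCORES):
    scores = np.asarray(scores, float)
    y = intercept + slope * scores
    if noise is not None:
        y = y + noise
    return pd.DataFrame(
        {"subject": "S", "score": scores, "mean_cbf": y, "n_voxels": 10}
    )


class TestCbfByScore:
    def test_uniform_cbf_reports_uniform_means(self, rng):
        scores = rng.choice(TIGR_SCORES[:5], size=(6, 6, 6))
        tm = tigr_from_scores(scores)
        cbf = Volume(np.full((6, 6, 6), 30.0), np.eye(4))
        rows = cbf_by_score(cbf, tm)
        assert (rows["mean_cbf"] == 30.0).all()
        assert set(rows["score"]) == set(np.unique(scores))

    def test_two_score_lesion_yields_two_rows(self):
        scores = np.zeros((4, 4, 4))
        scores[0, 0, 0] = 0.1
        scores[1, 1, 1] = 1.0
        rows = cbf_by_score(Volume(np.full((4, 4, 4), 5.0), np.eye(4)), tigr_from_scores(scores))
        assert len(rows) == 2

    def test_linear_construction_recovered(self, rng):
        """CBF built as 40 - 20*(score-0.1) is reproduced per-score exactly."""
        scores = rng.choice(TIGR_SCORES, size=(8, 8, 8))
        cbf = 40.0 - 20.0 * (scores - 0.1)
        rows = cbf_by_score(Volume(cbf, np.eye(4)), tigr_from_scores(scores))
        np.testing.assert_allclose(rows["mean_cbf"], 40.0 - 20.0 * (rows["score"] - 0.1))

    def test_missing_cbf_voxels_excluded(self):
        scores = np.full((3, 3, 3), 0.5)
        cbf = np.full((3, 3, 3), 12.0)
        cbf[0] = np.nan
        rows = cbf_by_score(Volume(cbf, np.eye(4)), tigr_from_scores(scores))
        assert rows.iloc[0]["n_voxels"] == 18


class TestScoreRegression:
    def test_collinear_points_give_perfect_fit(self):
        res = fit_score_regression(rows_from_line())
        assert res.r2 == pytest.approx(1.0)
        assert res.p_value < 1e-12
        assert res.slope == pytest.approx(-20.0)
        assert res.slope_sign == "-"

    def test_ten_rows_give_df_1_8(self, rng):
        res = fit_score_regression(rows_from_line(noise=rng.normal(0, 2, 10)))
        assert res.df == (1, 8)

    def test_f_identity_closed_form(self):
        """F = (n-2) R^2/(1-R^2): R^2=0.02 at n=10 gives F=0.16."""
        f = 8 * 0.02 / 0.98
        assert round(f, 2) == 0.16
        # and the fitted F obeys the same identity
        rng = np.random.default_rng(5)
        res = fit_score_regression(rows_from_line(slope=-1.0, noise=rng.normal(0, 6, 10)))
        assert res.f_stat == pytest.approx(8 * res.r2 / (1 - res.r2), rel=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        """OLS line fit agrees with the hand-derived closed form on random data."""
        for _ in range(30):
            n = int(rng.integers(4, 11))
            scores = np.asarray(TIGR_SCORES[:n], float)
            y = rng.normal(30, 8, n)
            res = fit_score_regression(
                pd.DataFrame({"subject": "S", "score": scores, "mean_cbf": y, "n_voxels": 1})
            )
            xm, ym = scores.mean(), y.mean()
            slope = ((scores - xm) * (y - ym)).sum() / ((scores - xm) ** 2).sum()
            intercept = ym - slope * xm
            ss_res = ((y - intercept - slope * scores) ** 2).sum()
            ss_tot = ((y - ym) ** 2).sum()
            r2 = 1 - ss_res / ss_tot
            assert res.slope == pytest.approx(slope, rel=1e-8)
            assert res.r2 == pytest.approx(r2, rel=1e-8)
            assert res.f_stat == pytest.approx((n - 2) * r2 / (1 - r2), rel=1e-8)

    def test_constant_predictor_rejected(self):
        df = pd.DataFrame({"subject": "S", "score": [0.5] * 5, "mean_cbf": range(5), "n_voxels": 1})
        with pytest.raises(ValueError, match="constant"):
            fit_score_regression(df)


class TestBonferroni:
    def test_p_of_one_never_significant(self):
        out = bonferroni_assess({"a": 1.0}, alpha=0.01, n_tests=14)
        assert not out["bonferroni_significant"].any()
        assert not out["uncorrected_significant"].any()

    def test_threshold_is_alpha_over_n(self):
        out = bonferroni_assess({"a": 0.0005, "b": 0.0008}, alpha=0.01, n_tests=14)
        assert out.attrs["threshold"] == pytest.approx(0.01 / 14)
        assert bool(out.loc["a", "bonferroni_significant"])
        assert not bool(out.loc["b", "bonferroni_significant"])

    def test_familywise_error_controlled_under_null(self, rng):
        hits = 0
        reps = 2000
        for _ in range(reps):
            p = rng.uniform(size=14)
            out = bonferroni_assess(p, alpha=0.01, n_tests=14)
            hits += out["bonferroni_significant"].any()
        fwe = hits / reps
        # expected FWE = 1-(1-0.01/14)^14 ~ 0.00996; allow 3 MC SEs
        assert fwe <= 0.01 + 3 * np.sqrt(0.01 * 0.99 / reps)


class TestFactorModel:
    def make_table(self, n_subjects=14, seed=0, effects=None, noise=0.5):
        rng = np.random.default_rng(seed)
        effects = effects or {}
        rows = []
        sexes = ["F"] * 4 + ["M"] * (n_subjects - 4)
        rng.shuffle(sexes)
        for i in range(n_subjects):
            age = rng.uniform(24, 81)
            months = rng.uniform(9, 121)
            sex = sexes[i]
            base = 40.0 + effects.get("age", 0.0) * (age - 52.5)
            base += effects.get("months", 0.0) * (months - 65.0)
            base += effects.get("sex", 0.0) * (1 if sex == "F" else -1)
            for s in TIGR_SCORES:
                rows.append(
                    {
                        "subject": f"P{i}",
                        "score": s,
                        "mean_cbf": base
                        + effects.get("damage", 0.0) * (s - 0.55)
                        + rng.normal(0, noise),
                        "age": age,
                        "sex": sex,
                        "months_since_stroke": months,
                        "wab_aq": rng.uniform(27.4, 80.6),
                    }
                )
        return pd.DataFrame(rows)

    def test_140_rows_give_df_10_129(self):
        res = fit_factor_model(self.make_table())
        assert res.df == (10, 129)
        assert list(res.terms.index) == list(FACTOR_TERMS)

    def test_injected_signs_recovered(self):
        res = fit_factor_model(
            self.make_table(effects={"damage": -20.0, "age": 0.3, "sex": 3.0}, seed=1)
        )
        assert res.terms.loc["tissue_damage", "t"] < 0
        assert res.terms.loc["tissue_damage", "p"] < 1e-6
        assert res.terms.loc["age", "t"] > 0
        assert res.terms.loc["sex", "t"] > 0

    def test_wab_terms_appended(self):
        res = fit_factor_model(self.make_table(), include_wab=True)
        assert "wab_aq" in res.terms.index
        assert res.df[0] == 15

    def test_damage_estimate_matches_pooled_slope_without_demographic_effects(self):
        """With null demographics the damage coefficient is the pooled OLS slope."""
        table = self.make_table(effects={"damage": -20.0}, noise=0.2, seed=3)
        res = fit_factor_model(table)
        pooled = fit_score_regression(table[["subject", "score", "mean_cbf"]].assign(n_voxels=1))
        assert res.terms.loc["tissue_damage", "coef"] == pytest.approx(pooled.slope, rel=0.05)

    def test_single_sex_rejected(self):
        table = self.make_table()
        table["sex"] = "M"
        with pytest.raises(ValueError, match="sex"):
            fit_factor_model(table)

    def test_rank_deficiency_names_aliased_terms(self):
        table = self.make_table()
        table["months_since_stroke"] = table["age"]  # alias two factors
        with pytest.raises(ValueError, match="aliased"):
            fit_factor_model(table)


class TestPairedTest:
    def test_identical_vectors_give_zero(self):
        t, df, p = paired_tissue_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, df, p) == (0.0, 2, 1.0)

    def test_constant_shift_flagged(self):
        with pytest.raises(ValueError, match="constant"):
            paired_tissue_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])

    def test_matches_textbook_formula(self, rng):
        a = rng.normal(50, 5, 12)
        b = rng.normal(45, 5, 12)
        t, df, p = paired_tissue_test(a, b)
        d = a - b
        expected_t = d.mean() / (d.std(ddof=1) / np.sqrt(12))
        assert t == pytest.approx(expected_t, rel=1e-10)
        assert df == 11
        from scipy import stats as sps

        assert p == pytest.approx(2 * sps.t.sf(abs(expected_t), 11), rel=1e-10)


class TestGroupOverlap:
    def test_identical_masks_pass_threshold(self, rng):
        data = rng.random((6, 6, 6)) > 0.4
        masks = [Mask(data, np.eye(4)) for _ in range(14)]
        out = group_overlap_mask(masks, 10)
        np.testing.assert_array_equal(out.data, data)

    def test_disjoint_masks_give_empty(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0], b[1] = True, True
        out = group_overlap_mask([Mask(a, np.eye(4)), Mask(b, np.eye(4))], 2)
        assert out.n_voxels == 0

    def test_matches_per_voxel_counting_oracle(self, rng):
        masks = [Mask(rng.random((5, 5, 5)) > 0.5, np.eye(4)) for _ in range(7)]
        out = group_overlap_mask(masks, 4)
        counts = sum(m.data.astype(int) for m in masks)
        np.testing.assert_array_equal(out.data, counts >= 4)


class TestCovariateRemoval:
    def test_exact_linear_voxel_becomes_constant(self, rng):
        cov = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        maps = [Volume(np.full((3, 3, 3), 10.0 + 2.0 * c), np.eye(4)) for c in cov]
        out, sig = voxelwise_covariate_removal(maps, cov, alpha=0.05)
        assert sig.data.all()
        for m in out:
            np.testing.assert_allclose(m.data, 10.0 + 2.0 * cov.mean(), atol=1e-9)

    def test_null_alteration_fraction_near_alpha(self, rng):
        n_sub = 14
        maps = [Volume(rng.normal(0, 1, (12, 12, 12)), np.eye(4)) for _ in range(n_sub)]
        cov = rng.normal(0, 1, n_sub)
        _, sig = voxelwise_covariate_removal(maps, cov, alpha=0.05)
        frac = sig.data.mean()
        se = np.sqrt(0.05 * 0.95 / 12**3)
        assert frac == pytest.approx(0.05, abs=5 * se)

    def test_zero_variance_covariate_rejected(self, rng):
        maps = [Volume(rng.normal(size=(3, 3, 3)), np.eye(4)) for _ in range(4)]
        with pytest.raises(ValueError, match="variance"):
            voxelwise_covariate_removal(maps, np.ones(4))


class TestSubjectRecord:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            SubjectRecord("X", age=-1, sex="M", months_since_stroke=5, lesion_volume_mm3=10)
        with pytest.raises(ValueError):
            SubjectRecord(
                "X", age=50, sex="M", months_since_stroke=5,
                lesion_volume_mm3=10, cavitation_volume_mm3=20,
            )
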