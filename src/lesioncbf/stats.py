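"""Lesion-CBF statistics.

Per-subject: mean CBF per discrete damage score regressed on the score
(ordinary least squares), with Bonferroni-corrected significance across
subjects.  Group level: a factorial linear model of the per-(subject, score)
mean lesion CBF on tissue damage, time since stroke, age, sex, and all
pairwise cross-terms, plus paired tissue comparisons, a group overlap mask,
and voxelwise removal of lesion-derived covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .core_io import Mask, Volume, check_aligned
from .tigr import TIGR_SCORES, TigrMap

logger = logging.getLogger(__name__)

#: factorial-model terms in reporting order
FACTOR_TERMS = (
    "sex",
    "age",
    "age_x_months_since_stroke",
    "age_x_sex",
    "tissue_damage",
    "months_since_stroke",
    "tissue_damage_x_sex",
    "tissue_damage_x_age",
    "tissue_damage_x_months_since_stroke",
    "months_since_stroke_x_sex",
)

WAB_TERMS = (
    "wab_aq",
    "wab_aq_x_tissue_damage",
    "wab_aq_x_age",
    "wab_aq_x_sex",
    "wab_aq_x_months_since_stroke",
)


@dataclass(frozen=True)
class SubjectRecord:
    """Demographics and lesion descriptors for one subject."""

    id: str
    age: float
    sex: str
    months_since_stroke: float
    lesion_volume_mm3: float
    cavitation_volume_mm3: float = 0.0
    wab_aq: float | None = None

    def __post_init__(self) -> None:
        if self.age <= 0 or self.months_since_stroke < 0:
            raise ValueError("age must be positive and months since stroke >= 0")
        if self.sex not in ("M", "F"):
            raise ValueError("sex must be 'M' or 'F'")
        if self.cavitation_volume_mm3 > self.lesion_volume_mm3:
            raise ValueError("cavitation volume cannot exceed lesion volume")


@dataclass(frozen=True)
class RegressionResult:
    """One subject's CBF-vs-damage linear fit."""

    r2: float
    f_stat: float
    df: tuple
    p_value: float
    slope: float
    intercept: float

    @property
    def slope_sign(self) -> str:
        if self.slope < 0:
            return "-"
        if self.slope > 0:
            return "+"
        return "none"


@dataclass
class FactorModelResult:
    """Group factorial model: per-term t/p plus the overall F test."""

    terms: pd.DataFrame  # index: term; columns: coef, t, p
    f_stat: float
    df: tuple
    p_value: float
    r2: float


def cbf_by_score(cbf: Volume, tigr: TigrMap, subject: str = "S") -> pd.DataFrame:
    """Mean CBF over the lesion voxels at each discrete damage score.

    One row per score present in the lesion with at least one defined CBF
    voxel; scores with no defined voxels are omitted and logged.
    """
    check_aligned(cbf, tigr.scores)
    rows = []
    for score in TIGR_SCORES:
        mask = tigr.score_mask(score)
        values = cbf.data[mask.data]
        values = values[np.isfinite(values)]
        if values.size == 0:
            if mask.n_voxels:
                logger.info(
                    "subject %s: score %.1f has no defined CBF voxels; row omitted",
                    subject,
                    score,
                )
            continue
        rows.append(
            {
                "subject": subject,
                "score": score,
                "mean_cbf": float(values.mean()),
                "n_voxels": int(values.size),
            }
        )
    return pd.DataFrame(rows, columns=["subject", "score", "mean_cbf", "n_voxels"])


def fit_score_regression(rows: pd.DataFrame) -> RegressionResult:
    """OLS of per-score mean CBF on the damage score for one subject.

    Reports R^2, F with df (1, n-2), the two-sided p-value, and the slope in
    mL/100g/min per unit damage.
    """
    if len(rows) < 3:
        raise ValueError(f"need >= 3 score rows to fit a line, got {len(rows)}")
    x = rows["score"].to_numpy(float)
    y = rows["mean_cbf"].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError("damage score is constant; the regression is undefined")
    design = sm.add_constant(x)
    fit = sm.OLS(y, design).fit()
    return RegressionResult(
        r2=float(fit.rsquared),
        f_stat=float(fit.fvalue),
        df=(int(fit.df_model), int(fit.df_resid)),
        p_value=float(fit.f_pvalue),
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
    )


def bonferroni_assess(
    p_values, alpha: float = 0.01, n_tests: int | None = None
) -> pd.DataFrame:
    """Flag per-subject significance at the Bonferroni-corrected threshold.

    A subject is Bonferroni-significant when p < alpha / n_tests; the table
    also reports the uncorrected p < 0.05 flag.  ``n_tests`` defaults to the
    number of p-values supplied.
    """
    p = pd.Series(p_values, dtype=float)
    if n_tests is None:
        n_tests = len(p)
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    threshold = alpha / n_tests
    out = pd.DataFrame(
        {
            "p": p,
            "bonferroni_significant": p < threshold,
            "uncorrected_significant": p < 0.05,
        }
    )
    out.attrs["threshold"] = threshold
    return out


def _factor_design(
    table: pd.DataFrame, include_wab: bool, center: bool
) -> pd.DataFrame:
    required = {"mean_cbf", "score", "age", "sex", "months_since_stroke"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"factor table is missing columns: {sorted(missing)}")
    if table[list(required)].isna().any().any():
        raise ValueError("factor table contains missing values")
    sexes = set(table["sex"])
    if not {"M", "F"} <= sexes:
        raise ValueError("both sexes must be present to estimate a sex effect")

    # effects coding (F = +1, M = -1) keeps main effects interpretable in the
    # presence of interactions; continuous factors are mean-centred before
    # forming cross-products to reduce collinearity
    sex_e = np.where(table["sex"] == "F", 1.0, -1.0)

    def cont(col):
        v = table[col].to_numpy(float)
        return v - v.mean() if center else v

    age = cont("age")
    months = cont("months_since_stroke")
    damage = cont("score")
    X = pd.DataFrame(
        {
            "sex": sex_e,
            "age": age,
            "age_x_months_since_stroke": age * months,
            "age_x_sex": age * sex_e,
            "tissue_damage": damage,
            "months_since_stroke": months,
            "tissue_damage_x_sex": damage * sex_e,
            "tissue_damage_x_age": damage * age,
            "tissue_damage_x_months_since_stroke": damage * months,
            "months_since_stroke_x_sex": months * sex_e,
        },
        index=table.index,
    )
    if include_wab:
        if "wab_aq" not in table.columns or table["wab_aq"].isna().any():
            raise ValueError("include_wab requires a complete 'wab_aq' column")
        wab = cont("wab_aq")
        X["wab_aq"] = wab
        X["wab_aq_x_tissue_damage"] = wab * damage
        X["wab_aq_x_age"] = wab * age
        X["wab_aq_x_sex"] = wab * sex_e
        X["wab_aq_x_months_since_stroke"] = wab * months
    return X


def fit_factor_model(
    table: pd.DataFrame, include_wab: bool = False, center: bool = True
) -> FactorModelResult:
    """Fit mean lesion CBF on damage/demographics and their cross-terms.

    ``table`` holds one row per (subject, score) with columns ``mean_cbf``,
    ``score``, ``age``, ``sex``, ``months_since_stroke`` (plus ``wab_aq``
    when ``include_wab``).  Rows are weighted equally, so with 14 subjects
    and 10 scores the overall F test has df (10, 129).
    """
    X = _factor_design(table, include_wab, center)
    y = table["mean_cbf"].to_numpy(float)
    design = sm.add_constant(X)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        corr = np.corrcoef(X.to_numpy().T)
        aliased = sorted(
            {
                X.columns[j]
                for i in range(len(X.columns))
                for j in range(i + 1, len(X.columns))
                if abs(corr[i, j]) > 1 - 1e-10
            }
            | {c for c in X.columns if X[c].std() == 0}
        )
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
    fit = sm.OLS(y, design).fit()
    terms = pd.DataFrame(
        {
            "coef": fit.params[1:],
            "t": fit.tvalues[1:],
            "p": fit.pvalues[1:],
        }
    )
    return FactorModelResult(
        terms=terms,
        f_stat=float(fit.fvalue),
        df=(int(fit.df_model), int(fit.df_resid)),
        p_value=float(fit.f_pvalue),
        r2=float(fit.rsquared),
    )


def paired_tissue_test(values_a, values_b) -> tuple:
    """Paired t-test between two per-subject mean series.

    Returns (t, df, p).  Zero-variance differences (e.g. a constant shift of
    noise-free data) make the statistic undefined and raise an error.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("paired test needs two equal-length vectors of size >= 2")
    d = a - b
    if np.std(d, ddof=1) == 0:
        if np.all(d == 0):
            return 0.0, int(a.size - 1), 1.0
        raise ValueError(
            "differences are a nonzero constant (zero variance); paired t is undefined"
        )
    res = sps.ttest_rel(a, b)
    return float(res.statistic), int(a.size - 1), float(res.pvalue)


def group_overlap_mask(masks: list, min_n: int) -> Mask:
    """Voxels covered by at least ``min_n`` of the per-subject masks."""
    if not masks:
        raise ValueError("no masks supplied")
    first = masks[0]
    counts = np.zeros(first.data.shape, dtype=int)
    for m in masks:
        check_aligned(first, m)
        counts += m.data.astype(int)
    return Mask(counts >= min_n, first.affine, f"overlap_ge_{min_n}")


def voxelwise_covariate_removal(
    maps: list,
    covariate,
    alpha: float = 0.05,
) -> tuple:
    """Residualize each voxel on a per-subject scalar where it matters.

    For every voxel, CBF across subjects is regressed on the covariate; where
    the slope is significant at ``alpha`` (two-sided t test, df n-2) the
    values are replaced by residuals plus the voxel's grand mean, elsewhere
    left unchanged.  Returns (residualized maps, significance Mask).
    """
    cov = np.asarray(covariate, float)
    n = len(maps)
    if n < 3:
        raise ValueError("need at least 3 subjects to regress a covariate")
    if cov.shape != (n,):
        raise ValueError("one covariate value per subject is required")
    if np.std(cov) == 0:
        raise ValueError("covariate has zero variance")
    first = maps[0]
    for m in maps[1:]:
        check_aligned(first, m)
    stack = np.stack([m.data for m in maps], axis=-1)  # (x, y, z, subject)

    xc = cov - cov.mean()
    sxx = float((xc**2).sum())
    ymean = stack.mean(axis=-1)
    sxy = np.tensordot(stack, xc, axes=([-1], [0]))
    slope = sxy / sxx
    pred = ymean[..., None] + slope[..., None] * xc
    resid = stack - pred
    sse = (resid**2).sum(axis=-1)
    dof = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sse / dof / sxx)
        tstat = np.where(se > 0, slope / se, np.where(slope != 0, np.inf, 0.0))
    pvals = 2.0 * sps.t.sf(np.abs(tstat), dof)
    significant = pvals < alpha

    out = []
    for s in range(n):
        data = np.where(significant, resid[..., s] + ymean, stack[..., s])
        out.append(Volume(data, first.affine))
    return out, Mask(significant, first.affine, "covariate_significant")


def joined_score_table(score_tables: list, records: list) -> pd.DataFrame:
    """Join per-subject score/CBF rows to demographics for the group model."""
    demo = pd.DataFrame(
        [
            {
                "subject": r.id,
                "age": r.age,
                "sex": r.sex,
                "months_since_stroke": r.months_since_stroke,
                "wab_aq": r.wab_aq,
            }
            for r in records
        ]
    )
    rows = pd.concat(score_tables, ignore_index=True)
    return rows.merge(demo, on="subject", how="left", validate="many_to_one")
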