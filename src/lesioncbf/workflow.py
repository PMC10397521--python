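"""End-to-end per-subject and cohort analyses.

Chains the damage-mapping, perfusion, and statistics stages exactly as a
study would run them: T2w/T1w ratio -> normalization bounds -> damage
scores, pCASL censoring/subtraction/quantification under one smoothing
variant, per-score mean CBF, and the per-subject and group models.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import perfusion, stats, tigr
from .phantom import Cohort, Phantom


@dataclass
class SubjectAnalysis:
    """Everything one subject's analysis produces."""

    subject: str
    bounds: tigr.NormalizationBounds
    tigr_map: tigr.TigrMap
    pipeline: perfusion.PipelineResult
    score_table: pd.DataFrame
    regression: stats.RegressionResult


def analyze_subject(
    ph: Phantom,
    variant: str = "blur4_mni",
    subject: str = "S",
    censor: perfusion.CensorConfig | None = None,
) -> SubjectAnalysis:
    """Run one phantom subject through damage mapping, CBF, and regression."""
    ratio = tigr.ratio_map(ph.t2w, ph.t1w)
    bounds = tigr.normalization_bounds(
        ratio, ph.tissues["GM"], ph.tissues["CSF"], ph.lesion, ph.brain
    )
    tmap = tigr.tigr_score(ratio, bounds, ph.lesion)
    result = perfusion.run_pipeline(ph.series, ph.trace, ph.brain, variant, censor=censor)
    rows = stats.cbf_by_score(result.cbf, tmap, subject=subject)
    regression = stats.fit_score_regression(rows)
    return SubjectAnalysis(
        subject=subject,
        bounds=bounds,
        tigr_map=tmap,
        pipeline=result,
        score_table=rows,
        regression=regression,
    )


@dataclass
class CohortAnalysis:
    """Per-subject fits plus the joined table and group factorial model."""

    subjects: list
    joined: pd.DataFrame
    factor_model: stats.FactorModelResult


def analyze_cohort(cohort: Cohort, variant: str = "blur4_mni") -> CohortAnalysis:
    """Analyze every subject and fit the group damage/demographics model."""
    analyses = []
    tables = []
    for i, ph in enumerate(cohort.subjects):
        sid = cohort.demographics["subject"].iloc[i]
        a = analyze_subject(ph, variant=variant, subject=sid)
        analyses.append(a)
        tables.append(a.score_table)
    joined = pd.concat(tables, ignore_index=True).merge(
        cohort.demographics, on="subject", how="left", validate="many_to_one"
    )
    fm = stats.fit_factor_model(joined)
    return CohortAnalysis(subjects=analyses, joined=joined, factor_model=fm)
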