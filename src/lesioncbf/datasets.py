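"""Bundled reference tables from a 14-participant chronic-stroke cohort.

Two small tables accompany the package so that table-level statistics
(percent cavitation, Bonferroni significance counts, the F/R^2 identity)
can be recomputed without any image data:

* ``cohort_characteristics``: per-subject demographics, aphasia type, lesion
  and cavitation volumes (mm^3) and the reported percent cavitation.
* ``score_regression_reference``: per-subject, per-pipeline R^2, F and
  p-value of the linear fit of mean lesion CBF on the ten damage scores,
  plus the sign of the fitted slope.  p-values reported only as "< 0.0001"
  are stored at that bound with ``p_is_upper_bound = 1``.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("lesioncbf.data").joinpath(name)
    with ref.open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def load_cohort_characteristics() -> pd.DataFrame:
    """Per-subject demographics and lesion/cavitation volumes (mm^3)."""
    return _load("cohort_characteristics.tsv")


def load_score_regression_reference() -> pd.DataFrame:
    """Per-subject, per-pipeline CBF-vs-damage regression statistics."""
    df = _load("score_regression_reference.tsv")
    df["p_is_upper_bound"] = df["p_is_upper_bound"].astype(bool)
    return df
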