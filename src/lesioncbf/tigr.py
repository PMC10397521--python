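"""Tissue Integrity Gradation via T2w/T1w Ratio (TIGR) damage mapping.

The per-voxel T2w/T1w ratio rises as tissue degrades toward CSF-like fluid.
Normalizing it between a grey-matter reference (score 0.1, least damaged)
and a CSF reference (score 1.0, most damaged) — both measured in intact
contralesional anterior tissue — gives a damage score that is comparable
across subjects regardless of atrophy, head size, or coil loading.  Lesion
voxels are classified into ten discrete scores 0.1, 0.2, ..., 1.0; score
1.0 is necrotic cavitation, scores 0.1-0.9 the surrounding pericavitational
tissue that may still be viable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import (
    EmptyRoiError,
    Mask,
    Volume,
    anterior_half,
    check_aligned,
    contralesional_hemisphere,
    erode_mask,
)

#: the ten discrete damage scores
TIGR_SCORES = tuple(np.round(np.arange(1, 11) * 0.1, 1))


@dataclass(frozen=True)
class NormalizationBounds:
    """Reference mean ratios anchoring the damage scale.

    ``gm_ref`` (score 0.1) comes from the contralesional anterior GM ribbon
    eroded by one voxel; ``csf_ref`` (score 1.0) from the contralesional
    anterior lateral ventricle eroded by one voxel.
    """

    gm_ref: float
    csf_ref: float

    def __post_init__(self) -> None:
        if not (self.csf_ref > self.gm_ref > 0):
            raise ValueError(
                f"bounds must satisfy csf_ref > gm_ref > 0, got "
                f"gm_ref={self.gm_ref:g}, csf_ref={self.csf_ref:g}"
            )


@dataclass
class TigrMap:
    """Per-voxel damage scores: 0 outside the lesion, one of 0.1..1.0 inside."""

    scores: Volume
    lesion: Mask

    def __post_init__(self) -> None:
        check_aligned(self.scores, self.lesion)

    def score_mask(self, score: float) -> Mask:
        """Binary ROI of lesion voxels carrying one discrete score."""
        data = self.lesion.data & np.isclose(self.scores.data, score, atol=1e-6)
        return Mask(data, self.scores.affine, f"tigr_{score:.1f}")

    def score_counts(self) -> pd.Series:
        counts = {s: int(self.score_mask(s).n_voxels) for s in TIGR_SCORES}
        return pd.Series(counts, name="n_voxels")


def ratio_map(t2w: Volume, t1w: Volume, t1w_threshold: float = 1e-6) -> Volume:
    """Voxelwise T2w/T1w quotient; voxels with T1w <= threshold are missing."""
    check_aligned(t2w, t1w)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(t1w.data > t1w_threshold, t2w.data / t1w.data, np.nan)
    return Volume(ratio, t2w.affine)


def _reference_roi(tissue: Mask, contra: Mask, anterior: Mask, lesion: Mask, name: str) -> Mask:
    # erode the full tissue mask first so voxels at the quadrant cut planes
    # are not lost to the erosion, then restrict
    roi = erode_mask(tissue, 1)
    roi = Mask(roi.data & contra.data & anterior.data & ~lesion.data, tissue.affine, name)
    if not roi.data.any():
        raise EmptyRoiError(
            f"{name} reference ROI is empty after contralesional-anterior "
            "restriction and one-voxel erosion"
        )
    return roi


def normalization_bounds(
    ratio: Volume,
    gm: Mask,
    csf_ventricle: Mask,
    lesion: Mask,
    brain: Mask,
) -> NormalizationBounds:
    """Mean ratio in the eroded contralesional anterior GM and ventricle ROIs."""
    for m in (gm, csf_ventricle, lesion, brain):
        check_aligned(ratio, m)
    contra = contralesional_hemisphere(brain, lesion)
    ant = anterior_half(brain)
    gm_roi = _reference_roi(gm, contra, ant, lesion, "contralesional anterior GM")
    csf_roi = _reference_roi(
        csf_ventricle, contra, ant, lesion, "contralesional anterior ventricle CSF"
    )
    gm_ref = float(np.nanmean(ratio.data[gm_roi.data]))
    csf_ref = float(np.nanmean(ratio.data[csf_roi.data]))
    if not csf_ref > gm_ref:
        raise ValueError(
            f"reference bounds out of order: CSF mean ratio ({csf_ref:g}) must "
            f"exceed GM mean ratio ({gm_ref:g})"
        )
    return NormalizationBounds(gm_ref=gm_ref, csf_ref=csf_ref)


def tigr_score(ratio: Volume, bounds: NormalizationBounds, lesion: Mask) -> TigrMap:
    """Classify lesion voxels into the ten damage scores.

    The continuous score ``0.1 + 0.9 * (r - gm_ref) / (csf_ref - gm_ref)``
    is clamped to [0.1, 1.0] and rounded to the nearest multiple of 0.1 with
    ties toward higher damage.  Lesion voxels with an undefined ratio are
    assigned 1.0 (a vanishing T1w signal indicates fluid).
    """
    check_aligned(ratio, lesion)
    scores = np.zeros(ratio.data.shape)
    r = ratio.data[lesion.data]
    c = 0.1 + 0.9 * (r - bounds.gm_ref) / (bounds.csf_ref - bounds.gm_ref)
    c = np.clip(c, 0.1, 1.0)
    # round-half-up onto the 0.1 grid (ties toward higher damage)
    binned = np.floor(c * 10.0 + 0.5 + 1e-9) / 10.0
    binned = np.clip(binned, 0.1, 1.0)
    binned[~np.isfinite(r)] = 1.0
    scores[lesion.data] = binned
    return TigrMap(Volume(scores, ratio.affine), lesion)


def cavitation_split(tigr: TigrMap) -> tuple:
    """Split the lesion into necrotic cavitation (1.0) and pericavitation (0.1-0.9)."""
    cav = tigr.lesion.data & np.isclose(tigr.scores.data, 1.0, atol=1e-6)
    peri = tigr.lesion.data & ~cav
    return (
        Mask(cav, tigr.scores.affine, "cavitation"),
        Mask(peri, tigr.scores.affine, "pericavitation"),
    )


def percent_cavitation(lesion_volume: float, cavitation_volume: float) -> float:
    """Cavitation volume as a percentage of lesion volume, to one decimal."""
    if lesion_volume <= 0:
        raise ValueError("percent cavitation is undefined for a zero lesion volume")
    if not (0 <= cavitation_volume <= lesion_volume):
        raise ValueError("cavitation volume must lie in [0, lesion volume]")
    return round(100.0 * cavitation_volume / lesion_volume, 1)


def tigr_summary(tigr: TigrMap, bounds: NormalizationBounds) -> pd.DataFrame:
    """Per-score voxel counts and volumes plus the bounds, as a tidy table."""
    voxvol = float(abs(np.linalg.det(tigr.scores.affine[:3, :3])))
    counts = tigr.score_counts()
    df = pd.DataFrame(
        {
            "score": list(counts.index),
            "n_voxels": counts.to_numpy(),
            "volume_mm3": counts.to_numpy() * voxvol,
        }
    )
    df.attrs["gm_ref"] = bounds.gm_ref
    df.attrs["csf_ref"] = bounds.csf_ref
    cav, _ = cavitation_split(tigr)
    df.attrs["percent_cavitation"] = percent_cavitation(
        tigr.lesion.volume_mm3, cav.volume_mm3
    )
    return df
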