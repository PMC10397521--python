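"""ROI-based quality metrics for CBF maps: SNR, CoV, and GM-WM CNR.

All three metrics are built from ROI means and standard deviations of the
quantified CBF map (sample SD, n-1 denominator):

    SNR = mu_tissue / sigma_air
    CoV = sigma_tissue / mu_tissue
    CNR = (mu_GM - mu_WM) / sigma_air

The tissue ROI is conventionally a 15 mm sphere in the anterior cingulate
cortex intersected with the GM / WM segmentations; the noise ROI is a 15 mm
sphere placed in air outside the head.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import EmptyRoiError, Mask, Volume, check_aligned

#: anterior cingulate sphere centre in template coordinates (x, y, z) mm
DEFAULT_ACC_CENTER = (0.0, 44.0, 18.0)
DEFAULT_ROI_RADIUS_MM = 15.0


class QcError(ValueError):
    """A quality metric is undefined for the supplied ROI statistics."""


@dataclass(frozen=True)
class RoiStats:
    """Mean, sample SD and defined-voxel count of a CBF ROI."""

    mu: float
    sigma: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("an ROI must contain at least one defined voxel")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass(frozen=True)
class QcReport:
    snr: float
    cov: float
    cnr: float
    tissue: RoiStats
    air: RoiStats
    gm: RoiStats
    wm: RoiStats

    def to_dict(self) -> dict:
        return {
            "snr": self.snr,
            "cov": self.cov,
            "cnr": self.cnr,
            "sd_convention": "sample (n-1)",
            "tissue": vars(self.tissue).copy(),
            "air": vars(self.air).copy(),
            "gm": vars(self.gm).copy(),
            "wm": vars(self.wm).copy(),
        }


def roi_stats(cbf: Volume, roi: Mask) -> RoiStats:
    """Mean and sample SD of the CBF over the ROI's defined (non-NaN) voxels."""
    check_aligned(cbf, roi)
    values = cbf.data[roi.data]
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise EmptyRoiError(f"ROI '{roi.label}' contains no defined voxels")
    sigma = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return RoiStats(mu=float(values.mean()), sigma=sigma, n=int(values.size))


def snr(tissue: RoiStats, air: RoiStats) -> float:
    """Signal-to-noise ratio: tissue mean over air SD."""
    if air.sigma <= 0:
        raise QcError("SNR is undefined: air ROI has zero SD")
    return tissue.mu / air.sigma


def cov(tissue: RoiStats) -> float:
    """Coefficient of variation: ROI SD over ROI mean."""
    if tissue.mu == 0:
        raise QcError("CoV is undefined: ROI mean is zero")
    return tissue.sigma / tissue.mu


def cnr(gm: RoiStats, wm: RoiStats, air: RoiStats) -> float:
    """Grey-to-white contrast-to-noise ratio: (mu_GM - mu_WM) / sigma_air."""
    if air.sigma <= 0:
        raise QcError("CNR is undefined: air ROI has zero SD")
    return (gm.mu - wm.mu) / air.sigma


def qc_report(
    cbf: Volume,
    tissue_roi: Mask,
    air_roi: Mask,
    gm_roi: Mask,
    wm_roi: Mask,
) -> QcReport:
    """Compute all three metrics from the four ROIs on one CBF map."""
    tissue = roi_stats(cbf, tissue_roi)
    air = roi_stats(cbf, air_roi)
    gm = roi_stats(cbf, gm_roi)
    wm = roi_stats(cbf, wm_roi)
    return QcReport(
        snr=snr(tissue, air),
        cov=cov(tissue),
        cnr=cnr(gm, wm, air),
        tissue=tissue,
        air=air,
        gm=gm,
        wm=wm,
    )
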