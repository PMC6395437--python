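"""ROI rules for lesion quantification.

Several small ROIs are placed inside the lesion; the one with the lowest
mean APTW is selected (theoretically the most acidic part of the infarct),
a contralateral normal-appearing white matter (CNAWM) ROI is obtained by
mirroring across the brain midline, and the APTW contrast is the lesion
value minus the CNAWM value. A whole-lesion mean is carried alongside as
the robustness comparator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import ROISet
from .pipeline import APTWMap

__all__ = [
    "LesionMeasurement",
    "roi_means",
    "lowest_roi",
    "mirror_roi",
    "measure_lesion",
]


@dataclass(frozen=True)
class LesionMeasurement:
    """Per-scan lesion quantification.

    ``lesion_aptw_pct`` follows the lowest-ROI rule; ``contrast_pct`` is
    exactly ``lesion_aptw_pct - cnawm_aptw_pct``.
    """

    lesion_aptw_pct: float
    lesion_aptw_mean_pct: float | None
    cnawm_aptw_pct: float
    contrast_pct: float
    n_rois: int
    selected_roi_index: int

    def __post_init__(self) -> None:
        expected = self.lesion_aptw_pct - self.cnawm_aptw_pct
        if not np.isclose(self.contrast_pct, expected, rtol=0, atol=1e-12):
            raise ValueError("contrast must equal lesion minus CNAWM exactly")


def roi_means(
    aptw: APTWMap,
    rois: list[np.ndarray],
    max_invalid_fraction: float = 0.2,
) -> list[float]:
    """Arithmetic mean of valid map voxels inside each ROI.

    ROIs whose invalid-voxel fraction exceeds ``max_invalid_fraction`` are
    still averaged over their valid part but trigger a warning; an ROI with
    no valid voxel is an error.
    """
    out = []
    for i, roi in enumerate(rois):
        roi = np.asarray(roi, bool)
        n_total = int(roi.sum())
        if n_total == 0:
            raise ValueError(f"ROI {i} is empty")
        valid = roi & aptw.mask
        n_valid = int(valid.sum())
        if n_valid == 0:
            raise ValueError(f"ROI {i} contains no valid voxels")
        if n_total - n_valid > max_invalid_fraction * n_total:
            warnings.warn(
                f"ROI {i}: {n_total - n_valid}/{n_total} voxels invalid",
                UserWarning,
                stacklevel=2,
            )
        out.append(float(aptw.value_pct[valid].mean()))
    return out


def lowest_roi(means: list[float]) -> tuple[float, int]:
    """Minimum ROI mean; ties broken by the lowest index."""
    if not means:
        raise ValueError("need at least one ROI mean")
    idx = int(np.argmin(means))  # argmin returns the first minimum
    return float(means[idx]), idx


def mirror_roi(
    roi: np.ndarray,
    midline_col: float | None = None,
) -> np.ndarray:
    """Mirror an ROI across a vertical midline.

    Pixel ``(r, c)`` maps to ``(r, round(2 * midline - c))``; the midline
    defaults to the vertical image center ``(width - 1) / 2``. Pixels that
    fall outside the image are dropped with a warning. Mirroring twice
    returns the original ROI.
    """
    roi = np.asarray(roi, bool)
    h, w = roi.shape
    if midline_col is None:
        midline_col = (w - 1) / 2.0
    rr, cc = np.nonzero(roi)
    cm = np.rint(2.0 * midline_col - cc).astype(int)
    inside = (cm >= 0) & (cm < w)
    if not inside.all():
        warnings.warn(
            f"{int((~inside).sum())} mirrored pixels fall outside the image and are dropped",
            UserWarning,
            stacklevel=2,
        )
    out = np.zeros_like(roi)
    out[rr[inside], cm[inside]] = True
    if not out.any():
        raise ValueError("mirrored ROI is empty")
    return out


def measure_lesion(
    aptw: APTWMap,
    roiset: ROISet,
    midline_col: float | None = None,
) -> LesionMeasurement:
    """Apply the full ROI protocol to one APTW map.

    The CNAWM value comes from ``roiset.cnawm_roi`` when present, otherwise
    from the mirror of the selected (lowest) lesion ROI. The whole-lesion
    mean uses ``roiset.whole_lesion_mask`` when present.
    """
    means = roi_means(aptw, roiset.lesion_rois)
    lesion_val, idx = lowest_roi(means)
    if roiset.cnawm_roi is not None:
        cnawm_mask = roiset.cnawm_roi
    else:
        cnawm_mask = mirror_roi(roiset.lesion_rois[idx], midline_col=midline_col)
    cnawm_val = roi_means(aptw, [cnawm_mask])[0]
    whole = (
        roi_means(aptw, [roiset.whole_lesion_mask])[0]
        if roiset.whole_lesion_mask is not None
        else None
    )
    return LesionMeasurement(
        lesion_aptw_pct=lesion_val,
        lesion_aptw_mean_pct=whole,
        cnawm_aptw_pct=cnawm_val,
        contrast_pct=lesion_val - cnawm_val,
        n_rois=len(means),
        selected_roi_index=idx,
    )
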