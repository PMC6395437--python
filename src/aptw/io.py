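"""On-disk artifacts and shared conventions for the APTW pipeline.

Conventions used throughout the package:

* images are 2D single-slice, pixel indexing is 0-based row-major ``(row, col)``;
* saturation offsets are in ppm relative to water, positive = downfield;
* APTW values are stored as percent of the bulk water signal (``S0``), i.e.
  ``MTRasym(3.5 ppm) * 100``;
* image series are NIfTI files with frames stacked along the third axis, in
  the order listed by the offset table with repeated acquisitions contiguous.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "OffsetTable",
    "ZSpectrumSeries",
    "ROISet",
    "CohortTable",
    "ROISizeWarning",
    "read_series",
    "read_roiset",
    "read_cohort",
    "write_maps",
    "read_maps",
    "default_offset_table",
]

#: Multi-offset, multi-acquisition sampling scheme of the default 31-offset
#: protocol: (offset in ppm, number of acquisitions). 61 frames in total, with
#: 8 repeats at +/-3.5 ppm where the amide resonance sits.
_DEFAULT_PROTOCOL: tuple[tuple[float, int], ...] = tuple(
    sorted(
        [(0.0, 1)]
        + [
            (s * off, n)
            for s in (+1.0, -1.0)
            for off, n in [
                (0.25, 1), (0.5, 1), (0.75, 1), (1.0, 2), (1.5, 2), (2.0, 2),
                (2.5, 2), (3.0, 2), (3.25, 2), (3.5, 8), (3.75, 2), (4.0, 2),
                (4.5, 1), (5.0, 1), (6.0, 1),
            ]
        ]
    )
)


class ROISizeWarning(UserWarning):
    """An ROI falls outside the advisory pixel-count bounds."""


@dataclass(frozen=True)
class OffsetTable:
    """Ordered table of saturation offsets and acquisition counts.

    Parameters
    ----------
    entries
        Sequence of ``(offset_ppm, n_acquisitions)`` pairs. Offsets must be
        unique; counts must be positive integers. The on-disk frame order is
        the entry order with repeats contiguous.
    reference_offset_ppm
        Offset of the registration reference frame (default +3.5 ppm).
    """

    entries: tuple[tuple[float, int], ...]
    reference_offset_ppm: float = 3.5

    def __post_init__(self) -> None:
        entries = tuple((float(o), int(n)) for o, n in self.entries)
        object.__setattr__(self, "entries", entries)
        offs = [o for o, _ in entries]
        if len(set(offs)) != len(offs):
            raise ValueError("offset table contains duplicate offsets")
        if any(n < 1 for _, n in entries):
            raise ValueError("acquisition counts must be positive integers")

    @classmethod
    def default_protocol(cls) -> "OffsetTable":
        """The 31-offset / 61-acquisition protocol."""
        return cls(entries=_DEFAULT_PROTOCOL)

    @property
    def offsets_ppm(self) -> np.ndarray:
        return np.array([o for o, _ in self.entries], dtype=float)

    @property
    def n_frames(self) -> int:
        return int(sum(n for _, n in self.entries))

    def expand(self) -> np.ndarray:
        """Per-frame offsets: each entry repeated ``n_acquisitions`` times."""
        return np.repeat(self.offsets_ppm, [n for _, n in self.entries])

    def collapse(self) -> "OffsetTable":
        """Same offsets with all acquisition counts set to 1."""
        return OffsetTable(
            entries=tuple((o, 1) for o, _ in self.entries),
            reference_offset_ppm=self.reference_offset_ppm,
        )

    def index_of(self, offset_ppm: float, tol: float = 1e-9) -> int:
        """Entry index of ``offset_ppm``; raises if absent."""
        d = np.abs(self.offsets_ppm - offset_ppm)
        i = int(np.argmin(d))
        if d[i] > tol:
            raise ValueError(f"offset {offset_ppm} ppm not in table")
        return i

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "offset_ppm": self.offsets_ppm,
                "n_acquisitions": [n for _, n in self.entries],
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, reference_offset_ppm: float = 3.5) -> "OffsetTable":
        df = pd.read_csv(path)
        missing = {"offset_ppm", "n_acquisitions"} - set(df.columns)
        if missing:
            raise ValueError(f"offset table CSV missing columns: {sorted(missing)}")
        return cls(
            entries=tuple(zip(df["offset_ppm"].astype(float), df["n_acquisitions"].astype(int))),
            reference_offset_ppm=reference_offset_ppm,
        )


def default_offset_table() -> OffsetTable:
    return OffsetTable.default_protocol()


@dataclass
class ZSpectrumSeries:
    """A saturated-image series plus its unsaturated normalization image.

    ``frames`` has shape ``(n_frames, H, W)`` and holds one image per
    acquisition; ``s0_image`` has shape ``(H, W)``.
    """

    frames: np.ndarray
    s0_image: np.ndarray
    offset_table: OffsetTable
    pixel_size_mm: tuple[float, float] = (2.2, 2.2)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.s0_image = np.asarray(self.s0_image, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, H, W) array")
        if self.s0_image.shape != self.frames.shape[1:]:
            raise ValueError(
                f"S0 shape {self.s0_image.shape} does not match frame shape "
                f"{self.frames.shape[1:]}"
            )
        if self.frames.shape[0] != self.offset_table.n_frames:
            raise ValueError(
                f"series has {self.frames.shape[0]} frames but the offset table "
                f"expands to {self.offset_table.n_frames} acquisitions"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.s0_image.shape  # type: ignore[return-value]

    @property
    def frame_offsets_ppm(self) -> np.ndarray:
        return self.offset_table.expand()

    def validate_s0(self, mask: np.ndarray | None = None) -> None:
        """Check that S0 is strictly positive on the analysis mask."""
        m = np.ones(self.shape, bool) if mask is None else np.asarray(mask, bool)
        if np.any(self.s0_image[m] <= 0):
            raise ValueError("S0 image is not strictly positive inside the analysis mask")

    def reference_frame_index(self) -> int:
        """Index of the first acquisition at the reference offset."""
        per_frame = self.frame_offsets_ppm
        ref = self.offset_table.reference_offset_ppm
        hits = np.nonzero(np.abs(per_frame - ref) < 1e-9)[0]
        if hits.size == 0:
            raise ValueError(f"reference offset {ref} ppm absent from the series")
        return int(hits[0])

    def to_files(self, series_path: str | Path, s0_path: str | Path, table_path: str | Path) -> None:
        _save_nifti(series_path, np.moveaxis(self.frames, 0, -1), self.pixel_size_mm)
        _save_nifti(s0_path, self.s0_image, self.pixel_size_mm)
        self.offset_table.to_csv(table_path)


def _save_nifti(path: str | Path, data: np.ndarray, pixel_size_mm: tuple[float, float] = (1.0, 1.0)) -> None:
    affine = np.diag([pixel_size_mm[0], pixel_size_mm[1], 1.0, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))


def _load_nifti(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata(), dtype=float)


def read_series(
    series_path: str | Path,
    s0_path: str | Path,
    offset_table_path: str | Path,
    mask: np.ndarray | None = None,
) -> ZSpectrumSeries:
    """Load and validate a saturated series, its S0 image and its offset table.

    The series NIfTI stacks frames along the third axis; the frame count must
    equal the expanded offset-table length. S0 must be strictly positive on
    ``mask`` (whole image if omitted with nonpositive voxels tolerated only
    outside an explicit mask).
    """
    for p in (series_path, s0_path, offset_table_path):
        if not Path(p).exists():
            raise FileNotFoundError(str(p))
    table = OffsetTable.from_csv(offset_table_path)
    frames = _load_nifti(series_path)
    if frames.ndim != 3:
        raise ValueError("series NIfTI must be 3D (H, W, n_frames)")
    frames = np.moveaxis(frames, -1, 0)
    s0 = _load_nifti(s0_path)
    if s0.ndim == 3 and s0.shape[-1] == 1:
        s0 = s0[..., 0]
    series = ZSpectrumSeries(frames=frames, s0_image=s0, offset_table=table)
    if mask is not None:
        series.validate_s0(mask)
    return series


@dataclass
class ROISet:
    """Lesion ROIs plus optional contralateral and whole-lesion masks."""

    lesion_rois: list[np.ndarray]
    cnawm_roi: np.ndarray | None = None
    whole_lesion_mask: np.ndarray | None = None
    size_bounds: tuple[int, int] = (100, 125)

    def __post_init__(self) -> None:
        self.lesion_rois = [np.asarray(r, bool) for r in self.lesion_rois]
        if self.cnawm_roi is not None:
            self.cnawm_roi = np.asarray(self.cnawm_roi, bool)
        if self.whole_lesion_mask is not None:
            self.whole_lesion_mask = np.asarray(self.whole_lesion_mask, bool)
        shapes = {r.shape for r in self.lesion_rois}
        for extra in (self.cnawm_roi, self.whole_lesion_mask):
            if extra is not None:
                shapes.add(extra.shape)
        if len(shapes) > 1:
            raise ValueError(f"ROI masks have mismatched shapes: {shapes}")
        if self.cnawm_roi is not None:
            for i, r in enumerate(self.lesion_rois):
                if np.any(r & self.cnawm_roi):
                    raise ValueError(f"lesion ROI {i} overlaps the CNAWM ROI")
        lo, hi = self.size_bounds
        for i, r in enumerate(self.lesion_rois):
            n = int(r.sum())
            if not lo <= n <= hi:
                warnings.warn(
                    f"lesion ROI {i} has {n} pixels, outside the advisory "
                    f"bounds [{lo}, {hi}]",
                    ROISizeWarning,
                    stacklevel=2,
                )

    def to_files(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for i, r in enumerate(self.lesion_rois):
            _save_nifti(d / f"lesion_roi_{i:02d}.nii", r.astype(np.uint8))
        if self.cnawm_roi is not None:
            _save_nifti(d / "cnawm_roi.nii", self.cnawm_roi.astype(np.uint8))
        if self.whole_lesion_mask is not None:
            _save_nifti(d / "whole_lesion.nii", self.whole_lesion_mask.astype(np.uint8))


def _read_mask(path: str | Path) -> np.ndarray:
    arr = _load_nifti(path)
    if arr.ndim == 3 and arr.shape[-1] == 1:
        arr = arr[..., 0]
    uniq = np.unique(arr)
    if not np.all(np.isin(uniq, [0.0, 1.0])):
        raise ValueError(f"mask {path} is not binary (values {uniq[:5]}...)")
    return arr.astype(bool)


def read_roiset(
    lesion_paths: Sequence[str | Path],
    cnawm_path: str | Path | None = None,
    whole_lesion_path: str | Path | None = None,
) -> ROISet:
    """Read binary ROI masks from NIfTI files into a validated :class:`ROISet`."""
    return ROISet(
        lesion_rois=[_read_mask(p) for p in lesion_paths],
        cnawm_roi=_read_mask(cnawm_path) if cnawm_path is not None else None,
        whole_lesion_mask=_read_mask(whole_lesion_path) if whole_lesion_path is not None else None,
    )


def write_maps(maps: dict[str, np.ndarray], directory: str | Path, units: dict[str, str] | None = None) -> None:
    """Write named voxel maps as NIfTI plus a JSON sidecar recording units."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    units = units or {}
    meta = {}
    for name, arr in maps.items():
        _save_nifti(d / f"{name}.nii", np.asarray(arr, float))
        meta[name] = {"units": units.get(name, ""), "file": f"{name}.nii"}
    (d / "maps.json").write_text(json.dumps(meta, indent=2))


def read_maps(directory: str | Path) -> dict[str, np.ndarray]:
    d = Path(directory)
    meta = json.loads((d / "maps.json").read_text())
    return {name: _load_nifti(d / info["file"]) for name, info in meta.items()}


#: Columns every cohort table must carry. One row per scan; ``nan`` in
#: ``post_treatment_time_h`` marks a pre-treatment scan.
COHORT_COLUMNS = (
    "patient_id",
    "scan_id",
    "nihss",
    "onset_time_h",
    "post_treatment_time_h",
    "treated",
    "effective",
    "lesion_aptw_pct",
    "cnawm_aptw_pct",
    "contrast_pct",
)


@dataclass
class CohortTable:
    """Per-scan cohort rows feeding the statistics layer.

    ``onset_time_h`` is the time since symptom onset *at that scan*;
    ``post_treatment_time_h`` is NaN for pre-treatment scans. APTW columns are
    in percent of the bulk water signal.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = set(COHORT_COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        df = self.df
        if (df["onset_time_h"] <= 0).any():
            raise ValueError("onset_time_h must be positive")
        nihss = df["nihss"].dropna()
        if ((nihss < 0) | (nihss > 42)).any():
            raise ValueError("NIHSS outside [0, 42]")
        pre = df[df["post_treatment_time_h"].isna()]
        if pre.groupby("patient_id").size().max() > 1:
            raise ValueError("more than one pre-treatment scan for some patient")

    @property
    def pre_treatment(self) -> pd.DataFrame:
        return self.df[self.df["post_treatment_time_h"].isna()]

    @property
    def post_treatment(self) -> pd.DataFrame:
        return self.df[self.df["post_treatment_time_h"].notna()]

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortTable":
        return cls(df=pd.read_csv(path))


def read_cohort(csv_path: str | Path) -> CohortTable:
    """Read and validate a per-scan cohort CSV."""
    return CohortTable.from_csv(csv_path)
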