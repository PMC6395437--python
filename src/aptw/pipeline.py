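"""Z-spectrum assembly, voxelwise B0 correction and MTR-asymmetry mapping.

Processing order: register the series to the +3.5 ppm reference frame,
average repeated acquisitions per offset, normalize by the unsaturated S0
image, estimate the per-voxel B0 shift as the spline-interpolated minimum of
the z-spectrum near water, re-interpolate each spectrum onto the nominal
offsets, and quantify with the asymmetry

    MTRasym(offset) = MTR(+offset) - MTR(-offset)
                    = [S_sat(-offset) - S_sat(+offset)] / S0,

whose value at +3.5 ppm (in percent of S0) is the APT-weighted (APTW)
signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .io import ZSpectrumSeries
from .registration import RigidTransform2D, register_series

__all__ = [
    "ZSpectrumStack",
    "B0Map",
    "APTWMap",
    "average_repeats",
    "normalize",
    "estimate_b0",
    "correct_b0",
    "mtr_asym",
    "compute_aptw_map",
    "mtr_asym_spectrum",
    "process_series",
    "PipelineResult",
]


@dataclass
class ZSpectrumStack:
    """Per-voxel z-spectra on the sorted unique nominal offsets.

    ``values`` has shape ``(n_offsets, H, W)`` holding ``S_sat/S_0``;
    voxels excluded from analysis carry ``mask == False``.
    """

    values: np.ndarray
    offsets_ppm: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.offsets_ppm = np.asarray(self.offsets_ppm, float)
        self.mask = np.asarray(self.mask, bool)
        if np.any(np.diff(self.offsets_ppm) <= 0):
            raise ValueError("offsets must be strictly increasing")
        if self.values.shape[0] != self.offsets_ppm.size:
            raise ValueError("one spectrum sample per offset required")
        if self.values.shape[1:] != self.mask.shape:
            raise ValueError("mask shape does not match image shape")

    def index_of(self, offset_ppm: float, tol: float = 1e-9) -> int:
        d = np.abs(self.offsets_ppm - offset_ppm)
        i = int(np.argmin(d))
        if d[i] > tol:
            raise ValueError(f"offset {offset_ppm} ppm is not on the nominal grid")
        return i


@dataclass
class B0Map:
    """Per-voxel static-field shift in ppm with a validity flag."""

    shift_ppm: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.shift_ppm = np.asarray(self.shift_ppm, float)
        self.valid = np.asarray(self.valid, bool)


@dataclass
class APTWMap:
    """APTW signal per voxel, in percent of the bulk water signal."""

    value_pct: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.value_pct = np.asarray(self.value_pct, float)
        self.mask = np.asarray(self.mask, bool)
        if not np.all(np.isfinite(self.value_pct[self.mask])):
            raise ValueError("non-finite APTW values inside the mask")


def average_repeats(series: ZSpectrumSeries) -> ZSpectrumSeries:
    """Arithmetic mean of repeated acquisitions, one frame per unique offset."""
    table = series.offset_table
    out = np.empty((len(table.entries), *series.shape))
    start = 0
    for i, (_, n) in enumerate(table.entries):
        out[i] = series.frames[start : start + n].mean(axis=0)
        start += n
    return ZSpectrumSeries(
        frames=out,
        s0_image=series.s0_image,
        offset_table=table.collapse(),
        pixel_size_mm=series.pixel_size_mm,
    )


def normalize(series: ZSpectrumSeries, mask: np.ndarray | None = None) -> ZSpectrumStack:
    """Divide the (repeat-averaged) frames by S0 voxelwise.

    Voxels with nonpositive S0 are flagged invalid (removed from the mask)
    rather than raising, so a stray background voxel cannot abort a run.
    """
    if any(n != 1 for _, n in series.offset_table.entries):
        series = average_repeats(series)
    mask = np.ones(series.shape, bool) if mask is None else np.asarray(mask, bool)
    good = mask & (series.s0_image > 0)
    order = np.argsort(series.offset_table.offsets_ppm)
    offsets = series.offset_table.offsets_ppm[order]
    with np.errstate(divide="ignore", invalid="ignore"):
        values = series.frames[order] / series.s0_image[None, :, :]
    values[:, ~good] = np.nan
    return ZSpectrumStack(values=values, offsets_ppm=offsets, mask=good)


def _per_voxel_spline_eval(
    x: np.ndarray, Y: np.ndarray, queries: np.ndarray
) -> np.ndarray:
    """Evaluate voxelwise cubic splines at per-voxel query points.

    ``Y`` is ``(n, V)`` (one spectrum per voxel, shared abscissa ``x``);
    ``queries`` is ``(V,)``. Queries are clamped to the sampled range.
    """
    cs = CubicSpline(x, Y, axis=0)
    q = np.clip(queries, x[0], x[-1])
    idx = np.clip(np.searchsorted(x, q, side="right") - 1, 0, len(x) - 2)
    dq = q - x[idx]
    c = cs.c  # (4, n-1, V)
    v = np.arange(Y.shape[1])
    return ((c[0, idx, v] * dq + c[1, idx, v]) * dq + c[2, idx, v]) * dq + c[3, idx, v]


def estimate_b0(
    stack: ZSpectrumStack,
    window_ppm: float = 1.0,
    grid_step_ppm: float = 0.01,
    method: str = "symmetry",
    search_ppm: float = 0.6,
) -> B0Map:
    """Per-voxel B0 shift from the z-spectrum water dip.

    The spectrum restricted to ``|offset| <= window_ppm`` is interpolated
    with a cubic spline. With ``method="argmin"`` the shift is the spline
    minimum on a ``grid_step_ppm`` grid — simple, but with the coarse
    (0.25 ppm) sampling of the default protocol its interpolation error
    oscillates with the true shift at the +/-0.01 ppm level. The default
    ``method="symmetry"`` instead locates the center about which the
    interpolated dip is most mirror-symmetric (the direct-saturation line is
    locally symmetric, as WASSR-style maximum-symmetry methods exploit),
    which averages the interpolation error over the window and is several
    times more accurate on the same samples. Voxels without an interior
    optimum are flagged invalid, as are voxels already excluded upstream.
    """
    sel = np.abs(stack.offsets_ppm) <= window_ppm + 1e-9
    if sel.sum() < 5:
        raise ValueError(
            f"B0 window +/-{window_ppm} ppm covers only {int(sel.sum())} offsets (need >= 5)"
        )
    x = stack.offsets_ppm[sel]
    if x[0] > -window_ppm + 1e-6 or x[-1] < window_ppm - 1e-6:
        raise ValueError("B0 search window extends beyond the sampled offsets")
    h, wd = stack.mask.shape
    Y = stack.values[sel].reshape(sel.sum(), -1)
    voxels = np.nonzero(stack.mask.ravel())[0]
    shift = np.zeros(h * wd)
    valid = np.zeros(h * wd, bool)
    cs = CubicSpline(x, Y[:, voxels], axis=0)
    if method == "argmin":
        grid = np.arange(-window_ppm, window_ppm + grid_step_ppm / 2, grid_step_ppm)
        curves = cs(grid)  # (n_grid, n_masked)
        amin = np.argmin(curves, axis=0)
        shift[voxels] = grid[amin]
        valid[voxels] = (amin > 0) & (amin < len(grid) - 1) & np.isfinite(curves).all(axis=0)
    elif method == "symmetry":
        step = 0.002
        grid = np.arange(-window_ppm, window_ppm + step / 2, step)
        curves = cs(grid).astype(np.float32)
        half_widths = np.arange(0.05, 0.45 * window_ppm / 1.0 + 1e-9, 0.05)
        d_idx = np.round(half_widths / step).astype(int)
        c_max = min(search_ppm, window_ppm - half_widths.max())
        sel_c = np.abs(grid) <= c_max + 1e-12
        centers = np.nonzero(sel_c)[0]
        metric = np.zeros((len(centers), curves.shape[1]), dtype=np.float32)
        buf = np.empty_like(metric)
        for d in d_idx:
            np.subtract(curves[centers + d], curves[centers - d], out=buf)
            buf *= buf
            metric += buf
        amin = np.argmin(metric, axis=0)
        shift[voxels] = grid[centers[amin]]
        valid[voxels] = (
            (amin > 0) & (amin < len(centers) - 1) & np.isfinite(curves).all(axis=0)
        )
    else:
        raise ValueError(f"unknown B0 method {method!r}")
    return B0Map(shift_ppm=shift.reshape(h, wd), valid=valid.reshape(h, wd))


def correct_b0(stack: ZSpectrumStack, b0map: B0Map) -> ZSpectrumStack:
    """Re-interpolate each voxel's spectrum onto the nominal offsets.

    A voxel with shift ``d`` has its measured spectrum displaced by ``d``;
    the corrected value at nominal offset ``x`` is the cubic interpolation of
    the measured spectrum at ``x + d``, with end offsets clamped to the
    nearest sampled value. Invalid voxels propagate as invalid.
    """
    h, w = stack.mask.shape
    good = stack.mask & b0map.valid
    voxels = np.nonzero(good.ravel())[0]
    Y = stack.values.reshape(stack.offsets_ppm.size, -1)[:, voxels]
    d = b0map.shift_ppm.ravel()[voxels]
    out = np.full_like(stack.values.reshape(stack.offsets_ppm.size, -1), np.nan)
    for j, xj in enumerate(stack.offsets_ppm):
        out[j, voxels] = _per_voxel_spline_eval(stack.offsets_ppm, Y, xj + d)
    return ZSpectrumStack(
        values=out.reshape(stack.values.shape), offsets_ppm=stack.offsets_ppm, mask=good
    )


def mtr_asym(stack: ZSpectrumStack, offset_ppm: float) -> np.ndarray:
    """``[S_sat(-offset) - S_sat(+offset)] / S0`` per voxel, as a fraction.

    Both ``+offset`` and ``-offset`` must be on the nominal grid; there is no
    silent interpolation. Antisymmetric in its argument and identically zero
    at offset 0.
    """
    ip = stack.index_of(+offset_ppm)
    im = stack.index_of(-offset_ppm)
    return stack.values[im] - stack.values[ip]


def compute_aptw_map(stack: ZSpectrumStack, offset_ppm: float = 3.5) -> APTWMap:
    """APTW map: MTRasym at 3.5 ppm scaled to percent of S0."""
    vals = 100.0 * mtr_asym(stack, offset_ppm)
    mask = stack.mask & np.isfinite(vals)
    vals = np.where(mask, vals, 0.0)
    return APTWMap(value_pct=vals, mask=mask)


def mtr_asym_spectrum(stack: ZSpectrumStack, roi: np.ndarray) -> pd.DataFrame:
    """ROI mean +/- standard error of MTRasym per positive offset (percent).

    Uses every positive nominal offset whose mirror is also sampled.
    """
    roi = np.asarray(roi, bool) & stack.mask
    n = int(roi.sum())
    if n == 0:
        raise ValueError("ROI is empty (or fully invalid)")
    rows = []
    for off in stack.offsets_ppm[stack.offsets_ppm > 0]:
        if not np.any(np.abs(stack.offsets_ppm + off) < 1e-9):
            continue
        vals = 100.0 * mtr_asym(stack, off)[roi]
        rows.append(
            {
                "offset_ppm": off,
                "mean_pct": float(np.mean(vals)),
                "se_pct": float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
                "n_voxels": n,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PipelineResult:
    """Everything the `process` stage produces for one series."""

    aptw: APTWMap
    b0: B0Map
    stack: ZSpectrumStack
    transforms: list[RigidTransform2D] = field(default_factory=list)


def process_series(
    series: ZSpectrumSeries,
    mask: np.ndarray | None = None,
    register: bool = True,
    b0_correct: bool = True,
) -> PipelineResult:
    """Registered, repeat-averaged, normalized, B0-corrected APTW mapping."""
    transforms: list[RigidTransform2D] = []
    if register:
        series, transforms = register_series(series)
    series = average_repeats(series)
    stack = normalize(series, mask=mask)
    if b0_correct:
        b0 = estimate_b0(stack)
        stack = correct_b0(stack, b0)
    else:
        b0 = B0Map(shift_ppm=np.zeros(stack.mask.shape), valid=stack.mask.copy())
    aptw = compute_aptw_map(stack)
    return PipelineResult(aptw=aptw, b0=b0, stack=stack, transforms=transforms)


def plot_mtr_asym_spectrum(spectra: dict[str, pd.DataFrame], ax=None):
    """Plot ROI-mean MTRasym spectra (one line +/- SE band per ROI label)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, df in spectra.items():
        ax.errorbar(df["offset_ppm"], df["mean_pct"], yerr=df["se_pct"], label=label)
    ax.set_xlabel("offset (ppm)")
    ax.set_ylabel("MTR$_{asym}$ (%)")
    ax.axhline(0, color="k", lw=0.5)
    ax.legend()
    return ax
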