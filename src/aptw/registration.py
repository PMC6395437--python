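"""Rigid-body 2D alignment of a z-spectrum series to its reference frame.

Every acquired frame is registered to the first saturated image at the
reference offset (+3.5 ppm by default) with a three-degree-of-freedom rigid
transform (tx, ty, rotation about the image center). The similarity metric
is the mean squared difference of intensity-standardized images after
bilinear resampling; optimization is a translation initialization by phase
cross-correlation followed by multi-start Powell refinement. Heavily
saturated frames near 0 ppm can lack contrast; a frame whose fit fails to
improve on the identity residual inherits the transform of the nearest
successfully registered frame in offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize
from skimage.registration import phase_cross_correlation

from .io import ZSpectrumSeries

__all__ = ["RigidTransform2D", "register_pair", "register_series", "mse_residual"]


@dataclass(frozen=True)
class RigidTransform2D:
    """Rotation by ``theta_deg`` about the image center, then translation.

    ``tx_px`` shifts along columns (x), ``ty_px`` along rows (y). Forward
    mapping of a pixel ``p`` (row, col): ``p' = R (p - c) + c + t``.
    """

    tx_px: float
    ty_px: float
    theta_deg: float

    @property
    def is_identity(self) -> bool:
        return self.tx_px == self.ty_px == self.theta_deg == 0.0

    def _rot(self) -> np.ndarray:
        th = np.deg2rad(self.theta_deg)
        return np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])

    def inverse(self) -> "RigidTransform2D":
        R = self._rot().T
        t = -R @ np.array([self.ty_px, self.tx_px])
        return RigidTransform2D(tx_px=float(t[1]), ty_px=float(t[0]), theta_deg=-self.theta_deg)

    def compose(self, first: "RigidTransform2D") -> "RigidTransform2D":
        """The transform equivalent to applying ``first`` then ``self``."""
        R2 = self._rot()
        t1 = np.array([first.ty_px, first.tx_px])
        t2 = np.array([self.ty_px, self.tx_px])
        t = R2 @ t1 + t2
        return RigidTransform2D(
            tx_px=float(t[1]), ty_px=float(t[0]), theta_deg=self.theta_deg + first.theta_deg
        )

    def apply(self, image: np.ndarray, order: int = 1) -> np.ndarray:
        """Resample ``image`` under the forward transform (bilinear default).

        Out-of-bounds pixels take the nearest edge value.
        """
        img = np.asarray(image, dtype=float)
        c = (np.array(img.shape) - 1) / 2.0
        R = self._rot()
        t = np.array([self.ty_px, self.tx_px])
        # output[o] = input[Rinv (o - c - t) + c]
        Rinv = R.T
        offset = c - Rinv @ (c + t)
        return ndimage.affine_transform(img, Rinv, offset=offset, order=order, mode="nearest")

    def params(self) -> tuple[float, float, float]:
        return (self.tx_px, self.ty_px, self.theta_deg)


def _standardize(img: np.ndarray) -> np.ndarray:
    sd = img.std()
    if sd == 0:
        raise ValueError("constant image: no gradient information to register on")
    return (img - img.mean()) / sd


def mse_residual(transform: RigidTransform2D, moving: np.ndarray, fixed: np.ndarray) -> float:
    """Mean squared difference between standardized fixed and transformed moving."""
    m = _standardize(np.asarray(moving, float))
    f = _standardize(np.asarray(fixed, float))
    return float(np.mean((transform.apply(m) - f) ** 2))


def register_pair(
    moving: np.ndarray,
    fixed: np.ndarray,
    theta_starts_deg: tuple[float, ...] = (-2.0, 0.0, 2.0),
) -> RigidTransform2D:
    """Estimate the rigid transform aligning ``moving`` onto ``fixed``.

    Returns the transform minimizing the standardized MSE; its residual never
    exceeds the identity-transform residual (identity is a fallback).
    """
    moving = np.asarray(moving, float)
    fixed = np.asarray(fixed, float)
    if moving.shape != fixed.shape:
        raise ValueError("moving and fixed images must share dimensions")
    m = _standardize(moving)
    f = _standardize(fixed)

    def obj(p: np.ndarray) -> float:
        t = RigidTransform2D(tx_px=p[0], ty_px=p[1], theta_deg=p[2])
        return float(np.mean((t.apply(m) - f) ** 2))

    # translation initialization: moving ~ shift of fixed by (dy, dx)
    shift_est, _, _ = phase_cross_correlation(f, m, upsample_factor=10)
    ty0, tx0 = float(shift_est[0]), float(shift_est[1])

    best_p, best_v = np.zeros(3), obj(np.zeros(3))
    for th0 in theta_starts_deg:
        res = minimize(
            obj,
            x0=np.array([tx0, ty0, th0]),
            method="Powell",
            options={"xtol": 1e-4, "ftol": 1e-8, "maxiter": 200},
        )
        if res.fun < best_v:
            best_p, best_v = res.x, float(res.fun)
    return RigidTransform2D(tx_px=float(best_p[0]), ty_px=float(best_p[1]), theta_deg=float(best_p[2]))


def register_series(
    series: ZSpectrumSeries,
    reference_offset_ppm: float | None = None,
    skip_window_ppm: float = 1.2,
    max_shift_px: float = 8.0,
    max_rot_deg: float = 5.0,
    snap_shift_px: float = 0.2,
    snap_rot_deg: float = 0.15,
) -> tuple[ZSpectrumSeries, list[RigidTransform2D]]:
    """Register every frame (and S0) to the reference saturated frame.

    The fixed image is the first acquisition at the reference offset; it is
    left untouched. Frames outside the water dip register directly against
    the reference. Frames inside ``|offset| < skip_window_ppm`` are
    dominated by direct water saturation and share almost no anatomical
    contrast with the reference, so each of them is instead registered
    against the already-resampled frame nearest in offset (working inward
    from the dip edge), whose contrast it resembles. A frame whose fit fails
    to improve on the identity residual against its target, or lands outside
    the plausibility bounds, inherits the transform of the nearest-in-offset
    successfully registered frame (identity if none succeeded). The S0 image
    is resampled with its own transform, estimated directly against the
    reference frame.

    Estimates smaller than the snap thresholds are replaced by the exact
    identity and the frame is passed through untouched: sub-resolution
    transforms carry no usable motion information, and resampling is not
    free — it smooths the frame relative to the unresampled S0, which
    perturbs the normalized spectra for no benefit.
    """
    table = series.offset_table
    if reference_offset_ppm is not None:
        from dataclasses import replace as _replace

        table = _replace(table, reference_offset_ppm=reference_offset_ppm)
        series = ZSpectrumSeries(
            frames=series.frames, s0_image=series.s0_image,
            offset_table=table, pixel_size_mm=series.pixel_size_mm,
        )
    ref_idx = series.reference_frame_index()
    fixed = series.frames[ref_idx]
    frame_offsets = series.frame_offsets_ppm
    n_frames = series.frames.shape[0]

    def plausible(t: RigidTransform2D) -> bool:
        return (
            abs(t.tx_px) <= max_shift_px
            and abs(t.ty_px) <= max_shift_px
            and abs(t.theta_deg) <= max_rot_deg
        )

    def snap(t: RigidTransform2D) -> RigidTransform2D:
        if (
            abs(t.tx_px) < snap_shift_px
            and abs(t.ty_px) < snap_shift_px
            and abs(t.theta_deg) < snap_rot_deg
        ):
            return RigidTransform2D(0.0, 0.0, 0.0)
        return t

    transforms: list[RigidTransform2D | None] = [None] * n_frames
    resampled: dict[int, np.ndarray] = {ref_idx: fixed}
    success = np.zeros(n_frames, dtype=bool)
    identity = RigidTransform2D(0.0, 0.0, 0.0)
    transforms[ref_idx] = identity
    success[ref_idx] = True

    outer = [j for j in range(n_frames) if j != ref_idx and abs(frame_offsets[j]) >= skip_window_ppm]
    for j in outer:
        t = snap(register_pair(series.frames[j], fixed))
        if plausible(t) and mse_residual(t, series.frames[j], fixed) <= mse_residual(
            identity, series.frames[j], fixed
        ):
            transforms[j] = t
            success[j] = True
            resampled[j] = t.apply(series.frames[j]) if not t.is_identity else series.frames[j]

    # dip frames: chain inward, each against the nearest-in-offset frame
    # that is already in the reference space
    inner = sorted(
        (j for j in range(n_frames) if j != ref_idx and abs(frame_offsets[j]) < skip_window_ppm),
        key=lambda j: -abs(frame_offsets[j]),
    )
    for j in inner:
        anchors = [k for k in resampled if k != j]
        anchor = min(anchors, key=lambda k: abs(frame_offsets[k] - frame_offsets[j]))
        target = resampled[anchor]
        t = snap(register_pair(series.frames[j], target))
        if plausible(t) and mse_residual(t, series.frames[j], target) <= mse_residual(
            identity, series.frames[j], target
        ):
            transforms[j] = t
            success[j] = True
            resampled[j] = t.apply(series.frames[j]) if not t.is_identity else series.frames[j]

    # fallback: nearest successfully registered frame in offset
    for j in range(n_frames):
        if transforms[j] is None:
            ok = np.nonzero(success)[0]
            if ok.size:
                nearest = ok[np.argmin(np.abs(frame_offsets[ok] - frame_offsets[j]))]
                transforms[j] = transforms[nearest]
            else:
                transforms[j] = identity

    out = np.empty_like(series.frames)
    for j, t in enumerate(transforms):
        if j in resampled:
            out[j] = resampled[j]
        else:
            out[j] = series.frames[j] if t.is_identity else t.apply(series.frames[j])

    s0_t = snap(register_pair(series.s0_image, fixed))
    if not plausible(s0_t) or mse_residual(s0_t, series.s0_image, fixed) > mse_residual(
        identity, series.s0_image, fixed
    ):
        s0_t = identity
    s0 = series.s0_image if s0_t.is_identity else s0_t.apply(series.s0_image)

    registered = ZSpectrumSeries(
        frames=out, s0_image=s0, offset_table=table, pixel_size_mm=series.pixel_size_mm
    )
    return registered, [t for t in transforms]  # type: ignore[list-item]
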