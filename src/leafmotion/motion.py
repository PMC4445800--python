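"""Differential (gradient-based) translation estimation between frames.

Each consecutive frame pair is modeled as a single 2-D translation of the
region of interest.  Writing the brightness-constancy residual
``f_t - v_x f_x - v_y f_y`` over the ROI and minimizing its sum of squares
gives the classic 2x2 normal equations

    M v = b,   M = sum f_s f_s^T,   b = sum f_s f_t,

with ``f_s = (f_x, f_y)`` the spatial gradient.  Derivatives are computed
with separable two-tap filters d = (0.5, -0.5) and p = (0.5, 0.5): the
spatial derivatives act on the temporal average of the two frames, the
temporal derivative on their (half-)difference, each smoothed with ``p``
along the remaining axes, restricted to the valid convolution region.

Sign convention: the returned vector is the displacement of the image
content from the earlier frame to the later one, so a pattern moving +1 px
down (+y, image coordinates) yields ``v_y = +1``.

The linearization holds for subpixel-to-small motion (roughly <= 2 px per
frame step); larger true shifts bias the estimate toward zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cropgrid import ImageStack
from .trace import Trace

__all__ = [
    "DerivativeField",
    "MotionVector",
    "MotionTrace",
    "compute_derivatives",
    "estimate_translation",
    "track_stack",
]

#: Smallest-eigenvalue floor for a well-conditioned solve, per ROI pixel.
EIG_FLOOR_PER_PIXEL = 1e-9

#: Maximum acceptable condition number of M.
MAX_CONDITION_NUMBER = 1e8

#: Minimum ROI pixel count for a meaningful solve.
DEFAULT_MIN_ROI_PIXELS = 25


@dataclass(frozen=True)
class DerivativeField:
    """Spatial and temporal derivative images over the valid region.

    All three arrays share one shape, one pixel smaller than the input
    frames along each axis (2x2 filter support, no padding).
    """

    f_x: np.ndarray
    f_y: np.ndarray
    f_t: np.ndarray

    def __post_init__(self) -> None:
        if not (self.f_x.shape == self.f_y.shape == self.f_t.shape):
            raise ValueError("derivative images must share one shape")


@dataclass(frozen=True)
class MotionVector:
    """One frame-pair translation estimate, in pixels per frame step."""

    v_x: float
    v_y: float
    condition_ok: bool


@dataclass(frozen=True)
class MotionTrace:
    """Per-pair displacement series for one plant.

    ``times`` are the frame-pair midpoints in hours; length is
    ``n_frames - 1``.  ``interpolated`` flags pairs whose solve was
    ill-conditioned and was filled by linear interpolation.
    """

    times: np.ndarray
    v_x_series: np.ndarray
    v_y_series: np.ndarray
    interpolated: np.ndarray
    sampling_interval: float  # minutes
    plant_id: str | None = None

    def __post_init__(self) -> None:
        n = self.times.size
        if not (self.v_x_series.size == self.v_y_series.size == self.interpolated.size == n):
            raise ValueError("motion trace arrays must share one length")

    def __len__(self) -> int:
        return int(self.times.size)

    def vertical_trace(self) -> Trace:
        """The vertical-motion series v_y(t) — the rhythm signal."""
        return Trace(self.times, self.v_y_series, self.sampling_interval, self.plant_id)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "plant_id": self.plant_id or "",
                "time_hours": self.times,
                "v_x": self.v_x_series,
                "v_y": self.v_y_series,
                "interpolated": self.interpolated.astype(int),
            }
        )
        df.to_csv(path, index=False, float_format="%.10g")


def _smooth_x(a: np.ndarray) -> np.ndarray:
    return 0.5 * (a[:, 1:] + a[:, :-1])


def _smooth_y(a: np.ndarray) -> np.ndarray:
    return 0.5 * (a[1:, :] + a[:-1, :])


def _diff_x(a: np.ndarray) -> np.ndarray:
    return 0.5 * (a[:, 1:] - a[:, :-1])


def _diff_y(a: np.ndarray) -> np.ndarray:
    return 0.5 * (a[1:, :] - a[:-1, :])


def compute_derivatives(frame_t: np.ndarray, frame_prev: np.ndarray) -> DerivativeField:
    """Spatial/temporal derivatives of a frame pair (valid region only).

    f_x and f_y are the two-tap derivative of the temporal average image,
    smoothed along the other axis; f_t is the half-difference image
    smoothed along both axes.  Output shape is (H-1, W-1).
    """
    frame_t = np.asarray(frame_t, dtype=float)
    frame_prev = np.asarray(frame_prev, dtype=float)
    if frame_t.shape != frame_prev.shape:
        raise ValueError(
            f"frame shapes differ: {frame_t.shape} vs {frame_prev.shape}"
        )
    if frame_t.ndim != 2 or min(frame_t.shape) < 2:
        raise ValueError("frames must be 2-D and at least 2x2")
    avg = 0.5 * (frame_t + frame_prev)
    dif = 0.5 * (frame_t - frame_prev)
    f_x = _smooth_y(_diff_x(avg))
    f_y = _smooth_x(_diff_y(avg))
    f_t = _smooth_y(_smooth_x(dif))
    return DerivativeField(f_x, f_y, f_t)


def _roi_slices(roi, shape: tuple[int, int]) -> tuple[slice, slice]:
    if roi is None:
        return slice(None), slice(None)
    x_min, y_min, width, height = roi
    if x_min < 0 or y_min < 0 or x_min + width > shape[1] or y_min + height > shape[0]:
        raise ValueError(f"ROI {roi} outside the valid derivative region {shape}")
    return slice(y_min, y_min + height), slice(x_min, x_min + width)


def estimate_translation(
    deriv: DerivativeField,
    roi: tuple[int, int, int, int] | None = None,
    *,
    min_pixels: int = DEFAULT_MIN_ROI_PIXELS,
) -> MotionVector:
    """Solve the 2x2 normal equations over the ROI.

    ``roi`` is an (x_min, y_min, width, height) rectangle in valid-region
    coordinates, or None for the full valid region (the natural default
    once frames are per-plant crops).  Returns ``condition_ok=False`` with
    NaN components when M is singular or badly conditioned — e.g. on
    textureless (constant) regions, where the translation is unobservable.
    """
    ys, xs = _roi_slices(roi, deriv.f_x.shape)
    fx = deriv.f_x[ys, xs].ravel()
    fy = deriv.f_y[ys, xs].ravel()
    ft = deriv.f_t[ys, xs].ravel()
    if fx.size == 0:
        raise ValueError("empty ROI")
    if fx.size < min_pixels:
        raise ValueError(f"ROI has {fx.size} px, fewer than minimum {min_pixels}")
    if not (np.all(np.isfinite(fx)) and np.all(np.isfinite(fy)) and np.all(np.isfinite(ft))):
        raise ValueError("non-finite derivative values in ROI")

    m_xx = float(fx @ fx)
    m_xy = float(fx @ fy)
    m_yy = float(fy @ fy)
    b_x = float(fx @ ft)
    b_y = float(fy @ ft)
    M = np.array([[m_xx, m_xy], [m_xy, m_yy]])

    eigs = np.linalg.eigvalsh(M)
    floor = EIG_FLOOR_PER_PIXEL * fx.size
    if eigs[0] < floor or eigs[1] / max(eigs[0], np.finfo(float).tiny) > MAX_CONDITION_NUMBER:
        return MotionVector(np.nan, np.nan, condition_ok=False)

    # Least-squares solve; negated so v is the content displacement from
    # the earlier to the later frame (+y down).
    sol = np.linalg.solve(M, np.array([b_x, b_y]))
    return MotionVector(float(-sol[0]), float(-sol[1]), condition_ok=True)


def _interp_nan(values: np.ndarray) -> np.ndarray:
    """Fill NaN runs by linear interpolation (edges held at nearest valid)."""
    out = values.copy()
    bad = ~np.isfinite(out)
    if bad.any():
        idx = np.arange(out.size)
        out[bad] = np.interp(idx[bad], idx[~bad], out[~bad])
    return out


def track_stack(
    stack: ImageStack,
    roi: tuple[int, int, int, int] | None = None,
    *,
    plant_id: str | None = None,
    min_pixels: int = DEFAULT_MIN_ROI_PIXELS,
) -> MotionTrace:
    """Track every consecutive frame pair of a stack.

    Ill-conditioned pairs are recorded as missing, then filled by linear
    interpolation from neighboring pairs and flagged.  Raises when no pair
    at all is trackable (e.g. a featureless stack).
    """
    n = len(stack)
    if n < 2:
        raise ValueError("stack needs at least 2 frames")
    vx = np.full(n - 1, np.nan)
    vy = np.full(n - 1, np.nan)
    for i in range(n - 1):
        deriv = compute_derivatives(stack.frames[i + 1], stack.frames[i])
        vec = estimate_translation(deriv, roi, min_pixels=min_pixels)
        if vec.condition_ok:
            vx[i] = vec.v_x
            vy[i] = vec.v_y
    bad = ~np.isfinite(vy)
    if bad.all():
        raise ValueError(
            "no trackable content: every frame pair was ill-conditioned"
        )
    step_h = stack.sampling_interval / 60.0
    times = (np.arange(n - 1) + 0.5) * step_h
    return MotionTrace(
        times=times,
        v_x_series=_interp_nan(vx),
        v_y_series=_interp_nan(vy),
        interpolated=bad,
        sampling_interval=stack.sampling_interval,
        plant_id=plant_id,
    )
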