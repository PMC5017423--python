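"""Sub-pixel pillar tracking and calibrated deflection series.

Each pillar top is followed through the stack by normalised
cross-correlation of a fixed reference-frame template inside a local
search window, with the correlation peak localised to sub-pixel precision
by parabolic interpolation.  Positions relative to the pillar's relaxed
reference position, scaled by the pixel size, give the deflection time
series d_i = X_i - X_ref in micrometres; multiplying by the pillar spring
constant turns deflection into traction force.

Deflection vectors are reported in the physical (y-up) frame shared by the
whole package: an image-plane displacement of (0, -1) px is a +90 deg
deflection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from skimage.feature import match_template

from .detect import InsufficientDataError, PillarSet, select_reference_frame
from .mechanics import SpringConstant, force_from_deflection
from .stackio import ImageStack

__all__ = [
    "Trajectory",
    "DisplacementSeries",
    "track_pillars",
    "estimate_reference",
    "to_displacement",
    "to_force",
    "build_tracks_table",
]


@dataclass
class Trajectory:
    """Per-frame position of one pillar top, image coordinates (px)."""

    pillar_id: int
    positions_px: np.ndarray  # (T, 2) as (x, y)
    quality: np.ndarray  # (T,) correlation peak height
    lost: np.ndarray  # (T,) bool; True where position was interpolated

    @property
    def n_frames(self) -> int:
        return self.positions_px.shape[0]


@dataclass
class DisplacementSeries:
    """Calibrated deflection of one pillar relative to its reference.

    ``dx_um``/``dy_um`` are physical-frame components (y-up); ``d_um`` is
    the magnitude.  The reference may be a single position or, for the
    rolling-baseline method, one position per frame.
    """

    pillar_id: int
    reference_px: np.ndarray  # (2,) or (T, 2)
    pixel_size_um: float
    frame_rate_fps: float
    dx_um: np.ndarray
    dy_um: np.ndarray
    lost: np.ndarray
    reference_method: str = "percentile"

    @property
    def d_um(self) -> np.ndarray:
        return np.hypot(self.dx_um, self.dy_um)

    @property
    def reference_um(self) -> np.ndarray:
        return np.asarray(self.reference_px) * self.pixel_size_um

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.dx_um)) / self.frame_rate_fps


def _parabolic_offset(cm: float, c0: float, cp: float) -> float:
    """Sub-pixel offset of a parabola through three samples around a peak."""
    denom = cm - 2.0 * c0 + cp
    if denom >= 0:  # not a maximum; flat correlation
        return 0.0
    off = 0.5 * (cm - cp) / denom
    return float(np.clip(off, -1.0, 1.0))


def track_pillars(
    stack: ImageStack,
    pillars: PillarSet,
    window_px: float = 10.0,
    *,
    reference_frame: int | None = None,
    quality_threshold: float = 0.5,
) -> list[Trajectory]:
    """Track every pillar through the stack by template matching.

    Parameters
    ----------
    stack : ImageStack
    pillars : PillarSet
        Reference centres; templates are cut from the reference frame and
        never updated (pillar appearance is static).
    window_px : float
        Search half-width beyond the template, in px; must comfortably
        exceed the largest expected deflection.
    reference_frame : int, optional
        Frame the templates are cut from; defaults to the most relaxed
        frame (minimum deviation from the temporal median).
    quality_threshold : float
        Frames whose correlation peak falls below this are flagged lost
        and filled by linear interpolation from neighbouring good frames.
    """
    if len(pillars) == 0:
        raise ValueError("pillar set is empty")
    data = stack.data
    T, H, W = data.shape
    if reference_frame is None:
        reference_frame = select_reference_frame(data)
    ref_img = data[reference_frame].astype(float)

    th = int(np.ceil(pillars.radius_px + 2))  # template half-size
    sw = int(np.ceil(window_px))
    trajectories: list[Trajectory] = []

    for pid, (x0, y0) in zip(pillars.ids, pillars.centers_px):
        cx, cy = int(round(x0)), int(round(y0))
        tx0, ty0 = cx - th, cy - th
        if tx0 < 0 or ty0 < 0 or cx + th >= W or cy + th >= H:
            raise ValueError(
                f"pillar {pid} template at ({x0:.1f}, {y0:.1f}) exceeds frame bounds"
            )
        template = ref_img[ty0:cy + th + 1, tx0:cx + th + 1]

        sx0, sy0 = max(tx0 - sw, 0), max(ty0 - sw, 0)
        sx1, sy1 = min(cx + th + sw + 1, W), min(cy + th + sw + 1, H)

        positions = np.empty((T, 2))
        quality = np.empty(T)
        for i in range(T):
            search = data[i, sy0:sy1, sx0:sx1].astype(float)
            corr = match_template(search, template)
            pi, pj = np.unravel_index(np.argmax(corr), corr.shape)
            peak = float(corr[pi, pj])
            sub_x = sub_y = 0.0
            if 0 < pj < corr.shape[1] - 1:
                sub_x = _parabolic_offset(corr[pi, pj - 1], peak, corr[pi, pj + 1])
            if 0 < pi < corr.shape[0] - 1:
                sub_y = _parabolic_offset(corr[pi - 1, pj], peak, corr[pi + 1, pj])
            # shift of the template's top-left corner vs the reference frame
            shift_x = (sx0 + pj + sub_x) - tx0
            shift_y = (sy0 + pi + sub_y) - ty0
            positions[i] = (x0 + shift_x, y0 + shift_y)
            quality[i] = peak

        lost = quality < quality_threshold
        if lost.any() and not lost.all():
            good = np.flatnonzero(~lost)
            idx = np.arange(T)
            for ax in range(2):
                positions[lost, ax] = np.interp(idx[lost], good, positions[good, ax])
        trajectories.append(Trajectory(int(pid), positions, quality, lost))
    return trajectories


def _principal_axis(points: np.ndarray) -> np.ndarray:
    """Unit vector of the dominant motion direction (largest eigenvector)."""
    centered = points - points.mean(axis=0)
    cov = centered.T @ centered
    _, vecs = np.linalg.eigh(cov)
    return vecs[:, -1]


def estimate_reference(
    trajectory: Trajectory,
    method: str = "percentile",
    *,
    percentile: float = 10.0,
    frame_index: int = 0,
    window_frames: int = 50,
) -> np.ndarray:
    """Relaxed reference position X_ref for a trajectory.

    Methods
    -------
    ``percentile`` (default)
        Positions are projected on the trajectory's principal motion axis,
        oriented so contractions point positive (the projection is skewed
        toward the contracted side because beats are brief); the reference
        is the low ``percentile`` of the projection — the relaxed extreme.
        Robust to where in the beat cycle the recording starts.
    ``fixed-frame``
        The position at ``frame_index`` (the "original position" notion).
    ``rolling``
        A per-frame baseline: rolling low percentile of the axial
        projection over ``window_frames``; tolerates slow drift.

    Returns a (2,) position, or (T, 2) for the rolling method.
    """
    P = trajectory.positions_px
    if method == "fixed-frame":
        return P[frame_index].copy()
    if trajectory.lost.all():
        raise InsufficientDataError(
            f"pillar {trajectory.pillar_id}: every frame is lost"
        )
    if trajectory.n_frames < 10:
        raise InsufficientDataError("reference estimation needs >= 10 frames")
    good = ~trajectory.lost
    center = P[good].mean(axis=0)
    axis = _principal_axis(P[good])
    s = (P - center) @ axis
    if sps.skew(s[good]) < 0:  # orient contraction positive
        axis, s = -axis, -s
    ortho = np.array([-axis[1], axis[0]])
    u = (P - center) @ ortho

    if method == "percentile":
        s_ref = np.percentile(s[good], percentile)
        u_ref = np.median(u[good])
        return center + axis * s_ref + ortho * u_ref
    if method == "rolling":
        # greyscale opening in time: a rolling low quantile strips the beat
        # pulses, and a rolling high quantile of that result undoes the
        # systematic lag the first pass acquires under a monotone drift
        # (for a linear drift the two passes cancel exactly when the window
        # covers at least one full beat period)
        q = percentile / 100.0
        s_series = pd.Series(np.where(good, s, np.nan))
        eroded = (s_series.rolling(window_frames, center=True, min_periods=1)
                  .quantile(q))
        s_roll = (eroded.rolling(window_frames, center=True, min_periods=1)
                  .quantile(1.0 - q).to_numpy())
        u_ref = np.median(u[good])
        return center[None, :] + s_roll[:, None] * axis[None, :] + u_ref * ortho
    raise ValueError(f"unknown reference method {method!r}")


def to_displacement(
    trajectory: Trajectory,
    reference_px: np.ndarray,
    pixel_size_um: float,
    frame_rate_fps: float,
    *,
    reference_method: str = "percentile",
) -> DisplacementSeries:
    """Calibrated deflection series d_i = (X_i - X_ref) * pixel size.

    The y component is negated so deflections live in the physical y-up
    frame (image rows increase downward).
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    ref = np.asarray(reference_px, dtype=float)
    delta = trajectory.positions_px - ref  # broadcasts for (T,2) references
    return DisplacementSeries(
        pillar_id=trajectory.pillar_id,
        reference_px=ref,
        pixel_size_um=pixel_size_um,
        frame_rate_fps=frame_rate_fps,
        dx_um=delta[:, 0] * pixel_size_um,
        dy_um=-delta[:, 1] * pixel_size_um,
        lost=trajectory.lost.copy(),
        reference_method=reference_method,
    )


def to_force(series: DisplacementSeries, k: SpringConstant | float) -> np.ndarray:
    """Per-frame traction force magnitude in uN, F_i = k d_i."""
    return force_from_deflection(series.d_um, k, pillar_id=series.pillar_id)


def build_tracks_table(
    trajectories: list[Trajectory],
    series: list[DisplacementSeries],
    k: SpringConstant | float | None = None,
) -> pd.DataFrame:
    """Tidy per-pillar per-frame table, one row per (pillar, frame)."""
    parts = []
    for traj, ser in zip(trajectories, series):
        t = ser.times_s
        part = pd.DataFrame({
            "pillar_id": traj.pillar_id,
            "frame": np.arange(traj.n_frames),
            "time_s": t,
            "x_px": traj.positions_px[:, 0],
            "y_px": traj.positions_px[:, 1],
            "dx_um": ser.dx_um,
            "dy_um": ser.dy_um,
            "d_um": ser.d_um,
            "quality": traj.quality,
            "lost": traj.lost,
        })
        part["force_un"] = to_force(ser, k) if k is not None else np.nan
        parts.append(part)
    cols = ["pillar_id", "frame", "time_s", "x_px", "y_px", "dx_um", "dy_um",
            "d_um", "force_un", "quality", "lost"]
    return pd.concat(parts, ignore_index=True)[cols]
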