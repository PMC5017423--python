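"""Pillar-top localisation in a reference frame.

Pillar tops image as bright, roughly circular blobs on a dark background.
Detection is a band-pass (difference-of-Gaussians) response followed by
non-maximum suppression at the expected pillar separation, then sub-pixel
refinement by intensity-weighted centroid inside a radius-sized window.
Manual seeding is also supported for the workflow where the user clicks
the pillars to follow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.filters import gaussian

__all__ = [
    "PillarSet",
    "LatticeFit",
    "detect_pillars",
    "accept_manual_seeds",
    "fit_lattice",
    "select_reference_frame",
    "DegenerateInputError",
    "InsufficientDataError",
]


class DegenerateInputError(ValueError):
    """Frame carries no usable signal (constant or saturated)."""


class InsufficientDataError(ValueError):
    """Too few observations for the requested estimate."""


@dataclass
class LatticeFit:
    """Square-lattice QC fit: pitch, orientation, per-centre residuals."""

    pitch_px: float
    orientation_deg: float
    residuals_px: np.ndarray


@dataclass
class PillarSet:
    """The tracked pillar set: ids, sub-pixel reference centres, scores."""

    ids: np.ndarray
    centers_px: np.ndarray  # (N, 2) as (x, y), image convention
    radius_px: float
    scores: np.ndarray
    lattice: LatticeFit | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.centers_px = np.atleast_2d(np.asarray(self.centers_px, dtype=float))
        self.scores = np.asarray(self.scores, dtype=float)
        if len(set(self.ids.tolist())) != len(self.ids):
            raise ValueError("pillar ids must be unique")

    def __len__(self) -> int:
        return len(self.ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pillar_id": self.ids,
            "x_px": self.centers_px[:, 0],
            "y_px": self.centers_px[:, 1],
            "radius_px": self.radius_px,
            "score": self.scores,
        })

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PillarSet":
        radius = float(df["radius_px"].iloc[0]) if len(df) else 1.0
        return cls(
            ids=df["pillar_id"].to_numpy(),
            centers_px=df[["x_px", "y_px"]].to_numpy(float),
            radius_px=radius,
            scores=df["score"].to_numpy(float),
        )


def select_reference_frame(data: np.ndarray) -> int:
    """Index of the most relaxed frame: minimum absolute deviation from
    the temporal median image over the moving pixels.

    During diastole all pillars sit at rest, which is also where the stack
    spends most of its time.  A per-frame activity score is the absolute
    deviation from the temporal median image, summed over the top-decile
    temporal-variance pixels (the moving pillar edges; elsewhere the
    deviation is pure sensor noise and would swamp the motion signal).
    The reference is the middle frame of the longest low-activity run:
    the midpoint of a diastolic interval sits at true rest, whereas the
    single lowest-activity frame can fall on a contraction flank because
    the median image itself is slightly displaced by the relaxation tail.
    """
    data = data.astype(float)
    if data.shape[0] == 1:
        return 0
    med = np.median(data, axis=0)
    var = data.var(axis=0)
    mask = var >= np.quantile(var, 0.9)
    dev = np.abs(data[:, mask] - med[mask][None]).sum(axis=1)
    if np.ptp(dev) == 0:  # static scene: any frame serves
        return 0
    low = dev <= np.quantile(dev, 0.4)
    # longest consecutive run of low-activity frames
    best_start = best_len = cur_start = cur_len = 0
    for i, flag in enumerate(low):
        if flag:
            if cur_len == 0:
                cur_start = i
            cur_len += 1
            if cur_len > best_len:
                best_start, best_len = cur_start, cur_len
        else:
            cur_len = 0
    return int(best_start + best_len // 2)


def _refine_centroid(frame: np.ndarray, x: float, y: float,
                     radius: float, n_iter: int = 3,
                     max_shift: float | None = None
                     ) -> tuple[float, float, float]:
    """Intensity-weighted centroid in a window of half-size ~radius.

    Iterated so the window recentres on the estimate; weights are the
    window intensities above the window floor.  ``max_shift`` caps how far
    the estimate may wander from the starting point (used for manual seeds,
    which must not silently latch onto a neighbouring pillar).  Returns
    refined (x, y) and a contrast score: the intensity at the refined
    point above the window floor (near zero when the point sits on
    background, even if the window clips a neighbouring blob).
    """
    h, w = frame.shape
    x_anchor, y_anchor = x, y
    half = int(np.ceil(radius))
    score = 0.0
    for _ in range(n_iter):
        cx, cy = int(round(x)), int(round(y))
        x0, x1 = max(cx - half, 0), min(cx + half + 1, w)
        y0, y1 = max(cy - half, 0), min(cy + half + 1, h)
        window = frame[y0:y1, x0:x1].astype(float)
        if window.size == 0:
            return x, y, 0.0
        weights = window - window.min()
        total = weights.sum()
        score = float(frame[min(max(int(round(y)), 0), h - 1),
                            min(max(int(round(x)), 0), w - 1)] - window.min())
        if total <= 0:
            return x, y, 0.0
        yy, xx = np.mgrid[y0:y1, x0:x1]
        x = float((weights * xx).sum() / total)
        y = float((weights * yy).sum() / total)
        if max_shift is not None:
            dx, dy = x - x_anchor, y - y_anchor
            shift = np.hypot(dx, dy)
            if shift > max_shift:
                x = x_anchor + dx * max_shift / shift
                y = y_anchor + dy * max_shift / shift
    return x, y, score


def _row_major_order(centers: np.ndarray, row_tol: float) -> np.ndarray:
    """Sort centres top-to-bottom then left-to-right, grouping rows
    whose y coordinates agree within ``row_tol``."""
    order = np.argsort(centers[:, 1], kind="stable")
    rows = np.zeros(len(centers), dtype=int)
    row = 0
    for prev, cur in zip(order[:-1], order[1:]):
        if centers[cur, 1] - centers[prev, 1] > row_tol:
            row += 1
        rows[cur] = row
    return np.lexsort((centers[:, 0], rows))


def detect_pillars(
    reference_frame: np.ndarray,
    expected_radius_px: float,
    min_separation_px: float | None = None,
    *,
    invert: bool = False,
    threshold_rel: float = 0.2,
) -> PillarSet:
    """Locate bright pillar tops in a single frame.

    Parameters
    ----------
    reference_frame : 2-D array
        Frame taken between contractions (see :func:`select_reference_frame`).
    expected_radius_px : float
        Approximate pillar-top radius; sets the band-pass scales and the
        centroid window.
    min_separation_px : float, optional
        Non-maximum-suppression distance; defaults to 2x the radius.
    invert : bool
        Set for dark-on-bright contrast.
    threshold_rel : float
        Peak threshold relative to the strongest band-pass response.
    """
    frame = np.asarray(reference_frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError(f"expected a single 2-D frame, got shape {frame.shape}")
    if expected_radius_px < 1:
        raise ValueError("expected_radius_px must be >= 1")
    if frame.max() == frame.min():
        raise DegenerateInputError("frame is constant; nothing to detect")
    if invert:
        frame = frame.max() - frame
    if min_separation_px is None:
        min_separation_px = 2.0 * expected_radius_px

    # band-pass: difference of Gaussians tuned to the blob scale
    lo = gaussian(frame, sigma=expected_radius_px / 2.0, preserve_range=True)
    hi = gaussian(frame, sigma=expected_radius_px * 2.0, preserve_range=True)
    response = lo - hi

    # significance floor: a peak must clear the noise level of the band-pass
    # response, otherwise a featureless noisy frame would always yield its
    # global maximum as a spurious detection.  Pixel noise is estimated
    # robustly from the high-frequency residual (immune to scene structure)
    # and propagated through the DoG filter's L2 norm.
    residual = frame - gaussian(frame, sigma=1.0, preserve_range=True)
    sigma_px = 1.4826 * np.median(np.abs(residual - np.median(residual)))
    s1, s2 = expected_radius_px / 2.0, expected_radius_px * 2.0
    dog_norm = np.sqrt(1.0 / (4 * np.pi * s1**2) + 1.0 / (4 * np.pi * s2**2)
                       - 1.0 / (np.pi * (s1**2 + s2**2)))
    # the residual of white noise after subtracting its sigma=1 smoothing has
    # variance (1 - 2 g(0) + ||g||^2) sigma^2; rescale the estimate accordingly
    corr = 1.0 / np.sqrt(1.0 - 2.0 / (2 * np.pi) + 1.0 / (4 * np.pi))
    floor = 8.0 * sigma_px * corr * dog_norm

    peaks = peak_local_max(
        response,
        min_distance=max(int(round(min_separation_px)), 1),
        threshold_rel=threshold_rel,
        threshold_abs=floor,
        exclude_border=False,
    )
    if len(peaks) == 0:
        warnings.warn("no pillars detected in reference frame")
        return PillarSet(np.array([], int), np.empty((0, 2)), expected_radius_px,
                         np.array([]))

    centers, scores = [], []
    peak_max = response.max()
    # centroid on a lightly smoothed frame: suppresses pixel noise without
    # biasing the symmetric blob centre
    smooth = gaussian(frame, sigma=max(expected_radius_px / 8.0, 1.0),
                      preserve_range=True)
    for py, px in peaks:
        x, y, _ = _refine_centroid(smooth, float(px), float(py), expected_radius_px)
        centers.append((x, y))
        scores.append(float(response[py, px] / peak_max))
    centers = np.asarray(centers)
    scores = np.asarray(scores)

    order = _row_major_order(centers, row_tol=min_separation_px / 2.0)
    centers, scores = centers[order], scores[order]
    return PillarSet(np.arange(len(centers)), centers, expected_radius_px, scores)


def accept_manual_seeds(points, reference_frame: np.ndarray,
                        radius_px: float = 16.0,
                        low_score_factor: float = 0.2) -> PillarSet:
    """Refine user-clicked seed points to sub-pixel centres.

    Ordering is preserved.  A seed whose local contrast falls below
    ``low_score_factor`` times the strongest seed's contrast is flagged
    with a warning but retained (its score records the weak evidence).
    """
    frame = np.asarray(reference_frame, dtype=float)
    points = np.atleast_2d(np.asarray(points, dtype=float)) if len(points) else \
        np.empty((0, 2))
    h, w = frame.shape
    centers, contrasts = [], []
    for i, (x, y) in enumerate(points):
        if not (0 <= x < w and 0 <= y < h):
            raise IndexError(
                f"seed point {i} at ({x}, {y}) lies outside the {w}x{h} frame"
            )
        rx, ry, contrast = _refine_centroid(frame, x, y, radius_px,
                                            max_shift=radius_px / 2.0)
        centers.append((rx, ry))
        contrasts.append(contrast)
    contrasts = np.asarray(contrasts, dtype=float)
    if len(contrasts) and contrasts.max() > 0:
        scores = contrasts / contrasts.max()
        for i, s in enumerate(scores):
            if s < low_score_factor:
                warnings.warn(
                    f"seed point {i} has low local contrast (score {s:.2f}); "
                    "retained but likely background"
                )
    else:
        scores = contrasts
    return PillarSet(
        np.arange(len(points)),
        np.asarray(centers) if len(centers) else np.empty((0, 2)),
        radius_px,
        scores,
    )


def fit_lattice(centers_px: np.ndarray) -> LatticeFit:
    """Least-squares square-lattice QC fit.

    Pitch is the median nearest-neighbour spacing; orientation is the
    axial mean of nearest-neighbour directions folded modulo 90 deg (a
    square lattice has four-fold symmetric bond directions); residuals are
    each centre's distance to the nearest ideal lattice node.
    """
    centers = np.atleast_2d(np.asarray(centers_px, dtype=float))
    if len(centers) < 4:
        raise InsufficientDataError("lattice fit requires at least 4 centers")
    spread = centers - centers.mean(axis=0)
    if np.linalg.matrix_rank(np.cov(spread.T)) < 2:
        raise InsufficientDataError("centers are collinear; lattice is degenerate")

    tree = cKDTree(centers)
    dists, idx = tree.query(centers, k=2)
    nn_dist = dists[:, 1]
    pitch = float(np.median(nn_dist))

    vecs = centers[idx[:, 1]] - centers
    angles = np.arctan2(vecs[:, 1], vecs[:, 0])
    # fold the four-fold bond symmetry: mean of exp(4 i theta)
    z = np.exp(4j * angles).mean()
    orientation = float(np.rad2deg(np.angle(z) / 4.0))

    # residuals: snap to the fitted lattice frame
    c, s = np.cos(np.deg2rad(orientation)), np.sin(np.deg2rad(orientation))
    rot = np.array([[c, s], [-s, c]])
    local = (centers - centers[0]) @ rot.T / pitch
    snapped = np.round(local)
    residuals = np.linalg.norm((local - snapped) @ rot * pitch, axis=1)
    return LatticeFit(pitch, orientation, residuals)
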