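"""Beat segmentation, per-beat force/direction, and alignment statistics.

A beat is one contraction event: the deflection magnitude d(t) rises from
rest, peaks, and relaxes.  Beats are found as prominent peaks of d(t);
per-beat amplitude is the peak deflection (which times the spring constant
gives the maximum instantaneous contraction force), and the per-beat
direction is the angle of the deflection vector at the peak.

Direction statistics come in two flavours.  The ordinary circular
resultant R measures concentration of the raw angles — but cells aligned
to grooves push pillars in *both* directions along one axis (a bimodal
90/270-deg pattern), for which R is near zero.  The axial order parameter
R2, the resultant of the doubled angles, is 1 for perfect uniaxial beating
regardless of sign, and its half-argument is the dominant axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .detect import InsufficientDataError
from .mechanics import SpringConstant, force_from_deflection
from .track import DisplacementSeries

__all__ = [
    "Beat",
    "Beats",
    "BeatFrequency",
    "AlignmentSummary",
    "segment_beats",
    "beat_frequency",
    "beat_direction",
    "alignment_summary",
    "beats_to_dataframe",
    "plot_alignment",
]


@dataclass
class Beat:
    """One contraction event of one pillar."""

    pillar_id: int
    index: int
    start_frame: int
    peak_frame: int
    end_frame: int
    amplitude_um: float
    peak_force_un: float | None
    angle_deg: float | None  # None when the peak deflection vector is zero
    peak_time_s: float = np.nan

    @property
    def frames(self) -> tuple[int, int, int]:
        return self.start_frame, self.peak_frame, self.end_frame

    def duration_s(self, frame_rate_fps: float) -> float:
        return (self.end_frame - self.start_frame) / frame_rate_fps


class Beats(list):
    """List of :class:`Beat` with a quiescence flag (no beats detected)."""

    def __init__(self, beats=(), quiescent: bool = False):
        super().__init__(beats)
        self.quiescent = quiescent


@dataclass
class BeatFrequency:
    """Beat rate; undefined (NaN, ``defined=False``) below two beats."""

    hz: float  # reciprocal median inter-peak interval
    count_rate_hz: float  # beats / recording duration
    n_beats: int
    defined: bool


def segment_beats(
    series: DisplacementSeries,
    min_amplitude_um: float = 0.5,
    min_separation_s: float = 0.3,
    *,
    k: SpringConstant | float | None = None,
) -> Beats:
    """Split a deflection series into individual contraction events.

    Peaks of d(t) with height and prominence at least ``min_amplitude_um``
    and spacing at least ``min_separation_s`` become beats; prominence
    (rather than absolute height alone) tolerates slow baseline drift.
    Beat boundaries extend to the nearest sub-threshold crossings on
    either side of the peak.  A series with no qualifying peak returns an
    empty, quiescent :class:`Beats`.
    """
    d = series.d_um
    fps = series.frame_rate_fps
    if len(d) < 2 * fps:
        raise ValueError("need at least 2 s of data to segment beats")
    distance = max(int(round(min_separation_s * fps)), 1)
    peaks, _ = find_peaks(d, height=min_amplitude_um,
                          prominence=min_amplitude_um, distance=distance)
    if len(peaks) == 0:
        return Beats([], quiescent=True)

    below = d < min_amplitude_um
    beats = Beats()
    for i, p in enumerate(peaks):
        pre = np.flatnonzero(below[:p])
        start = int(pre[-1]) if len(pre) else 0
        post = np.flatnonzero(below[p:])
        end = int(p + post[0]) if len(post) else len(d) - 1
        amp = float(d[p])
        beats.append(Beat(
            pillar_id=series.pillar_id,
            index=i,
            start_frame=start,
            peak_frame=int(p),
            end_frame=end,
            amplitude_um=amp,
            peak_force_un=(float(force_from_deflection(amp, k))
                           if k is not None else None),
            angle_deg=beat_direction(series, int(p)),
            peak_time_s=float(p) / fps,
        ))
    return beats


def beat_frequency(beats: Beats, duration_s: float) -> BeatFrequency:
    """Beating frequency: reciprocal median inter-peak interval.

    Also reports the coarser count/duration rate; below two beats the
    interval-based frequency is undefined (NaN, ``defined=False``).
    """
    n = len(beats)
    count_rate = n / duration_s if duration_s > 0 else np.nan
    if n < 2:
        return BeatFrequency(np.nan, count_rate, n, defined=False)
    times = np.sort([b.peak_time_s for b in beats])
    median_interval = float(np.median(np.diff(times)))
    return BeatFrequency(1.0 / median_interval, count_rate, n, defined=True)


def beat_direction(series: DisplacementSeries,
                   beat: "Beat | int") -> float | None:
    """Angle (deg, [0, 360), physical y-up frame) of the peak deflection.

    Accepts a :class:`Beat` or a raw peak frame index.  Returns None for a
    zero deflection vector (direction undefined).
    """
    peak_frame = beat.peak_frame if isinstance(beat, Beat) else beat
    dx, dy = series.dx_um[peak_frame], series.dy_um[peak_frame]
    if dx == 0 and dy == 0:
        return None
    return float(np.mod(np.degrees(np.arctan2(dy, dx)), 360.0))


@dataclass
class AlignmentSummary:
    """Circular and axial statistics of a set of beat directions.

    ``resultant_r`` is the ordinary circular resultant length (1 = all
    angles identical, 0 = balanced); ``axial_r2`` is the doubled-angle
    resultant, which ignores 180-deg flips and measures concentration
    along a single axis; ``dominant_axis_deg`` (in [0, 180)) is that axis.
    """

    bin_edges_deg: np.ndarray
    counts: np.ndarray
    circular_mean_deg: float
    resultant_r: float
    axial_r2: float
    dominant_axis_deg: float
    n: int

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "circular_mean_deg": self.circular_mean_deg,
            "resultant_r": self.resultant_r,
            "axial_r2": self.axial_r2,
            "dominant_axis_deg": self.dominant_axis_deg,
            "bin_edges_deg": self.bin_edges_deg.tolist(),
            "counts": self.counts.tolist(),
        }


def alignment_summary(angles_deg, n_bins: int = 36) -> AlignmentSummary:
    """Summarise beat directions with directional and axial statistics.

    The 36 x 10-deg histogram mirrors the familiar polar rose plot; axial
    statistics use angle doubling: R2 = |mean exp(2 i theta)| and the
    dominant axis is half the argument of that mean, folded into [0, 180).
    """
    angles = np.asarray([a for a in np.atleast_1d(angles_deg)
                         if a is not None and np.isfinite(a)], dtype=float)
    if angles.size == 0:
        raise InsufficientDataError("no valid angles to summarise")
    theta = np.deg2rad(np.mod(angles, 360.0))

    z1 = np.exp(1j * theta).mean()
    z2 = np.exp(2j * theta).mean()
    counts, edges = np.histogram(np.rad2deg(theta), bins=n_bins, range=(0, 360))
    return AlignmentSummary(
        bin_edges_deg=edges,
        counts=counts,
        circular_mean_deg=float(np.mod(np.degrees(np.angle(z1)), 360.0)),
        resultant_r=float(np.abs(z1)),
        axial_r2=float(np.abs(z2)),
        dominant_axis_deg=float(np.mod(np.degrees(np.angle(z2)) / 2.0, 180.0)),
        n=int(angles.size),
    )


def beats_to_dataframe(all_beats: list[Beats], frame_rate_fps: float) -> pd.DataFrame:
    """Tidy per-beat table across pillars."""
    rows = []
    for beats in all_beats:
        for b in beats:
            rows.append({
                "pillar_id": b.pillar_id,
                "beat_index": b.index,
                "t_start_s": b.start_frame / frame_rate_fps,
                "t_peak_s": b.peak_frame / frame_rate_fps,
                "t_end_s": b.end_frame / frame_rate_fps,
                "amp_um": b.amplitude_um,
                "peak_force_un": b.peak_force_un,
                "angle_deg": b.angle_deg,
            })
    cols = ["pillar_id", "beat_index", "t_start_s", "t_peak_s", "t_end_s",
            "amp_um", "peak_force_un", "angle_deg"]
    return pd.DataFrame(rows, columns=cols)


def plot_alignment(summary: AlignmentSummary, ax=None):
    """Polar rose plot of beat directions (counts per angular bin)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    centers = np.deg2rad(0.5 * (summary.bin_edges_deg[:-1]
                                + summary.bin_edges_deg[1:]))
    width = np.deg2rad(np.diff(summary.bin_edges_deg))
    ax.bar(centers, summary.counts, width=width, alpha=0.7)
    ax.set_title(
        f"n={summary.n}, R={summary.resultant_r:.2f}, "
        f"R2={summary.axial_r2:.2f}, axis={summary.dominant_axis_deg:.0f}°"
    )
    return ax
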