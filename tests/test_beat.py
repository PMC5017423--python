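import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pillarbeat.beat import (
    Beats,
    alignment_summary,
    beat_direction,
    beat_frequency,
    beats_to_dataframe,
    segment_beats,
)
from pillarbeat.detect import InsufficientDataError
from pillarbeat.simulate import TwitchWaveform, twitch_displacement
from pillarbeat.track import DisplacementSeries


def series_from_waveform(waveform, duration_s=10.0, fps=25.0, angle_deg=90.0,
                         pillar_id=0):
    """Analytic deflection series: the twitch pulse along one axis."""
    t = np.arange(int(round(duration_s * fps))) / fps
    d = twitch_displacement(waveform, t)
    theta = np.deg2rad(angle_deg)
    return DisplacementSeries(
        pillar_id=pillar_id, reference_px=np.zeros(2), pixel_size_um=0.5,
        frame_rate_fps=fps, dx_um=d * np.cos(theta), dy_um=d * np.sin(theta),
        lost=np.zeros(len(t), bool))


class TestSegmentBeats:
    def test_ten_beats_at_1hz_over_10s(self):
        ser = series_from_waveform(TwitchWaveform(amplitude_um=3.0))
        beats = segment_beats(ser, 0.5, 0.3)
        assert len(beats) == 10
        assert not beats.quiescent
        amps = np.array([b.amplitude_um for b in beats])
        np.testing.assert_allclose(amps, 3.0, rtol=0.05)

    def test_tracked_fixture_beats(self, tracked_small):
        """5 s of 1 Hz beating on every tracked pillar gives 5 beats each."""
        _, truth, _, _, series = tracked_small
        for ser in series:
            beats = segment_beats(ser, 0.5, 0.3)
            assert len(beats) == 5
            for b in beats:
                assert b.start_frame <= b.peak_frame <= b.end_frame
                assert abs(b.amplitude_um - 3.0) / 3.0 < 0.05

    def test_flat_series_is_quiescent(self):
        ser = series_from_waveform(TwitchWaveform(amplitude_um=0.0))
        beats = segment_beats(ser, 0.5, 0.3)
        assert len(beats) == 0 and beats.quiescent

    def test_merged_peaks_within_min_separation_count_once(self):
        fps = 25.0
        t = np.arange(100) / fps
        d = (2.0 * np.exp(-0.5 * ((t - 1.0) / 0.06) ** 2)
             + 1.5 * np.exp(-0.5 * ((t - 1.15) / 0.06) ** 2))
        ser = DisplacementSeries(0, np.zeros(2), 0.5, fps, d, np.zeros_like(d),
                                 np.zeros(100, bool))
        beats = segment_beats(ser, 0.5, min_separation_s=0.4)
        assert len(beats) == 1
        assert beats[0].amplitude_um == pytest.approx(d.max(), rel=1e-6)

    def test_scaling_series_and_threshold_together_is_invariant(self):
        ser = series_from_waveform(TwitchWaveform(amplitude_um=3.0))
        base = segment_beats(ser, 0.5, 0.3)
        ser_scaled = DisplacementSeries(
            0, ser.reference_px, ser.pixel_size_um, ser.frame_rate_fps,
            ser.dx_um * 7, ser.dy_um * 7, ser.lost)
        scaled = segment_beats(ser_scaled, 0.5 * 7, 0.3)
        assert [b.peak_frame for b in base] == [b.peak_frame for b in scaled]

    def test_durations_fit_in_recording(self):
        ser = series_from_waveform(TwitchWaveform(amplitude_um=3.0))
        beats = segment_beats(ser, 0.5, 0.3)
        total = sum(b.duration_s(ser.frame_rate_fps) for b in beats)
        assert total <= len(ser.d_um) / ser.frame_rate_fps

    def test_too_short_series_rejected(self):
        ser = series_from_waveform(TwitchWaveform(), duration_s=1.0)
        with pytest.raises(ValueError, match="2 s"):
            segment_beats(ser, 0.5, 0.3)


class TestBeatFrequency:
    def test_uniform_10_beats_in_10s_is_1hz(self):
        ser = series_from_waveform(TwitchWaveform(period_s=1.0))
        beats = segment_beats(ser, 0.5, 0.3)
        freq = beat_frequency(beats, 10.0)
        assert freq.defined
        assert freq.hz == pytest.approx(1.0, abs=0.02)
        assert freq.count_rate_hz == pytest.approx(1.0, abs=0.05)

    def test_1p25_hz_waveform(self):
        ser = series_from_waveform(TwitchWaveform(period_s=0.8, rise_s=0.16,
                                                  decay_s=0.32))
        beats = segment_beats(ser, 0.5, 0.3)
        freq = beat_frequency(beats, 10.0)
        assert freq.hz == pytest.approx(1.25, abs=0.05)

    def test_single_beat_undefined(self):
        ser = series_from_waveform(TwitchWaveform(period_s=1.0), duration_s=10.0)
        one = Beats(segment_beats(ser, 0.5, 0.3)[:1])
        freq = beat_frequency(one, 10.0)
        assert not freq.defined and np.isnan(freq.hz)


class TestBeatDirection:
    def test_axis_cases(self):
        for angle, (dx, dy) in [(90.0, (0, 3)), (180.0, (-1, 0)),
                                (0.0, (2, 0)), (270.0, (0, -5))]:
            ser = DisplacementSeries(0, np.zeros(2), 0.5, 25.0,
                                     np.array([0.0, dx]), np.array([0.0, dy]),
                                     np.zeros(2, bool))
            assert beat_direction(ser, 1) == pytest.approx(angle)

    def test_zero_vector_undefined(self):
        ser = DisplacementSeries(0, np.zeros(2), 0.5, 25.0, np.zeros(3),
                                 np.zeros(3), np.zeros(3, bool))
        assert beat_direction(ser, 1) is None

    def test_aligned_simulator_beats_point_along_axis(self, tracked_small):
        _, truth, _, _, series = tracked_small
        for ser in series:
            for b in segment_beats(ser, 0.5, 0.3):
                assert min(abs(b.angle_deg - 90.0),
                           abs(b.angle_deg - 270.0)) < 3.0


class TestAlignmentSummary:
    def test_identical_angles_fully_concentrated(self):
        s = alignment_summary([90.0] * 12)
        assert s.resultant_r == pytest.approx(1.0)
        assert s.axial_r2 == pytest.approx(1.0)
        assert s.dominant_axis_deg == pytest.approx(90.0)
        assert s.circular_mean_deg == pytest.approx(90.0)

    def test_antipodal_angles_axial_not_directional(self):
        """90/270 alternation: directional resultant vanishes but the axial
        order parameter is 1 with a 90 deg dominant axis — the signature of
        uniaxial beating."""
        angles = [90.0, 270.0] * 25
        s = alignment_summary(angles)
        assert s.resultant_r == pytest.approx(0.0, abs=1e-12)
        assert s.axial_r2 == pytest.approx(1.0)
        assert s.dominant_axis_deg == pytest.approx(90.0)

    def test_uniform_angles_no_axial_order(self):
        rng = np.random.default_rng(123)
        s = alignment_summary(rng.uniform(0, 360, 1000))
        assert s.axial_r2 < 0.1

    def test_histogram_counts_sum_to_n(self):
        rng = np.random.default_rng(5)
        angles = rng.uniform(0, 360, 137)
        s = alignment_summary(angles, n_bins=36)
        assert s.counts.sum() == 137
        assert len(s.bin_edges_deg) == 37

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 359.99), min_size=2, max_size=30),
           st.sets(st.integers(0, 29)))
    def test_axial_r2_invariant_to_180_flips(self, angles, flip_idx):
        flipped = [a + 180.0 if i in flip_idx else a
                   for i, a in enumerate(angles)]
        s1 = alignment_summary(angles)
        s2 = alignment_summary(flipped)
        assert s2.axial_r2 == pytest.approx(s1.axial_r2, abs=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(InsufficientDataError):
            alignment_summary([])


class TestBeatsTable:
    def test_schema(self):
        ser = series_from_waveform(TwitchWaveform(amplitude_um=3.0))
        beats = segment_beats(ser, 0.5, 0.3, k=0.04)
        df = beats_to_dataframe([beats], 25.0)
        assert list(df.columns) == ["pillar_id", "beat_index", "t_start_s",
                                    "t_peak_s", "t_end_s", "amp_um",
                                    "peak_force_un", "angle_deg"]
        assert len(df) == len(beats)
        np.testing.assert_allclose(df["peak_force_un"], df["amp_um"] * 0.04)
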