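# Methods

## Physical model

A PDMS micropillar is treated as a linear-elastic Euler–Bernoulli
cantilever of circular cross-section, loaded laterally at its free tip by
the cell. Its tip stiffness is

    k = 3 E I / L^3,   I = π D^4 / 64   ⇒   k = 3 π E D^4 / (64 L^3)

with diameter `D`, length `L` (both µm) and Young's modulus `E` (MPa).
The model assumes small deflections (tip displacement ≪ L), a point load
at the tip, and a homogeneous isotropic material; none of the nonlinear
large-deflection, shear (Timoshenko) or substrate-warping corrections are
applied. For the reference geometry (D = 16 µm, L = 48 µm, E = 0.5 MPa)
the formula gives k = 0.0436 N/m, i.e. 0.04 N/m to one significant
figure; the tip deflection is then converted framewise to force by
F = k·d. PDMS moduli outside 0.5–4 MPa trigger a warning (not an error)
because that range covers typical curing recipes; other elastomers remain
usable. An explicit `pillar.spring_constant_n_per_m` config key bypasses
the formula when the stiffness has been calibrated independently (e.g. by
AFM).

### Units contract

Geometry µm, modulus MPa, stiffness N/m, deflection µm, force µN,
time s, rates fps/Hz. 1 µm × 1 N/m = 1 µN, so no numeric factor appears
anywhere in the force conversion. All unit conversions are internal to
`mechanics`.

### Coordinate convention

Image coordinates: `x` = column (rightward), `y` = row (downward), origin
at the centre of pixel (0, 0). Physical angles are counterclockwise from
+x in the y-up frame, so an image displacement of (0, −1) px points at
90°. Every module shares this convention; `track.to_displacement` is the
single place where the y sign is flipped.

## Synthetic data generator

The simulator emulates the targeted acquisition: an inverted-microscope
video (default 25 fps, 0.5 µm/px) of a square pillar lattice (default
5×5, 23 µm pitch) whose bright tops twitch along per-pillar axes.

* **Twitch waveform** — raised-cosine rise over `rise_s` (default 0.2 s)
  to the amplitude (default 3 µm), then a decay of shape
  `(1−s)·exp(−3s)` over `decay_s` (default 0.4 s), which is monotone and
  returns exactly to baseline, then rest until the period (default 1 s)
  completes. Peak value, period and zero-at-phase-zero are contractual;
  the decay shape is an implementation choice. The defaults mirror the
  spatial/temporal scales of neonatal rat ventricular myocyte recordings
  on such arrays (≈1 Hz spontaneous beating, µm-scale deflections);
  beat rate is configurable and not asserted as a fact about any
  particular culture.
* **Direction field** — `aligned` mode gives every pillar the same axis
  (default 90°) with optional Gaussian jitter and an optional fraction of
  180°-flipped pillars (producing the bimodal 90°/270° axial pattern of
  groove-aligned cultures); `isotropic` mode draws axes uniformly.
* **Optics** — each pillar top renders as a uniform disk (default radius
  16 px = 8 µm) with an error-function edge profile of width
  `blur_sigma_px` (default 2 px), the standard closed-form stand-in for a
  Gaussian-PSF-blurred disk; additive Gaussian sensor noise; 16-bit
  quantisation. Default signal 1800 over background 200, so
  `noise_sd = 180` corresponds to SNR ≈ 10. Photon-limited (Poisson)
  statistics, photobleaching, out-of-plane motion, pillar-top groove
  texture and cell bodies are deliberately not modelled: tracker
  acceptance is defined at a stated SNR, not at sensor physics.

Ground truth records every true position, axis and parameter. Rendering
is bit-deterministic for a fixed seed; the noise stream is drawn
independently of the signal so mean intensity is monotone in signal
level at a fixed seed. Because the rendered blobs are radially symmetric
and noise is additive Gaussian, passing the recovery tests demonstrates
correctness of the geometry/arithmetic chain and robustness at the
stated SNR — not robustness to textured pillar tops, uneven
illumination, focus drift or occluding cells, which real recordings
contain.

## Detection

The reference frame is chosen automatically as the middle frame of the
longest low-activity run, where activity is the absolute deviation from
the temporal median image summed over the top-decile temporal-variance
pixels (the moving pillar edges). The midpoint-of-run rule matters: the
median image itself is slightly displaced from rest by the relaxation
tail, so the single lowest-deviation frame can sit on a contraction
flank.

Detection is difference-of-Gaussians band-pass (σ = r/2 and 2r for
expected radius r), non-maximum suppression at the expected separation,
and a significance floor of 8× the band-pass noise level (pixel noise
estimated robustly from the high-frequency residual and propagated
through the DoG filter's L2 norm — this keeps a featureless noisy frame
from yielding its global maximum as a detection). Centres are refined by
iterated intensity-weighted centroid on a lightly smoothed frame;
manual seed points get the same refinement with the excursion capped at
r/2 so a click can never silently latch onto a neighbouring pillar.
A square-lattice QC fit reports median nearest-neighbour pitch,
orientation (axial mean of bond angles folded mod 90°) and per-centre
residuals.

## Tracking and deflection

Templates are cut once from the reference frame (half-size r+2 px) and
never updated — pillar appearance is static, and template updating
accumulates drift. Each frame is searched by normalised
cross-correlation in a window extending `search_window_px` (default
10 px; must exceed the largest expected motion) beyond the template, and
the correlation peak is localised sub-pixel by separable parabolic
interpolation. Frames whose peak correlation falls below
`quality_threshold` (default 0.5) are flagged `lost` and filled by
linear interpolation — never silently dropped, so downstream beat
statistics can exclude them.

The relaxed reference position X_ref supports three estimators:

* `percentile` (default): positions are projected on the principal
  motion axis, oriented by the projection's skewness so contraction is
  positive (beats are brief, so the distribution is skewed toward the
  contracted side); the reference is the 10th percentile of the
  projection — the relaxed extreme — plus the median off-axis
  coordinate.
* `fixed-frame`: the position at a chosen frame (the "original
  position" notion).
* `rolling`: a per-frame baseline from a greyscale opening in time
  (rolling 10th percentile followed by a rolling 90th percentile of the
  result, default window 50 frames = 2 s). The second pass cancels the
  lag the first pass acquires under monotone drift; for a linear drift
  the cancellation is exact once the window covers a full beat period.

Deflection is d_i = (X_i − X_ref)·pixel_size with the y component
negated into the physical frame; force is F_i = k·d_i.

## Beat analysis

Beats are peaks of the deflection magnitude d(t) with height and
prominence ≥ `min_beat_amplitude_um` (default 0.5 µm — comfortably above
tracking noise, well below physiological amplitudes) and spacing
≥ `min_beat_separation_s` (default 0.3 s, i.e. a 3.3 Hz ceiling).
Prominence rather than raw height tolerates baseline drift. Beat
boundaries extend to the nearest sub-threshold crossings. Per-beat
direction is the angle of the deflection vector at the peak frame
(per-frame vectors are available from the tracks table for users who
prefer them). Beating frequency is the reciprocal median inter-peak
interval (robust to a single missed beat), with the count/duration rate
reported alongside.

Direction sets are summarised with both the ordinary circular resultant
R = |⟨e^{iθ}⟩| and the axial order parameter R₂ = |⟨e^{2iθ}⟩| with
dominant axis ½·arg⟨e^{2iθ}⟩ ∈ [0°, 180°). Both are reported because
groove-aligned beating is an axial property: pillars on a shared axis
deflect toward 90° *and* 270°, for which R ≈ 0 while R₂ = 1 — a purely
directional mean would misreport perfect alignment as disorder. The
default 36 × 10° histogram matches conventional polar rose plots.

## Group statistics

Per-experiment summary values are reported as mean ± SEM (sample sd with
the n−1 denominator over √n); SEM is undefined (NaN) at n = 1.
Two-group comparisons use pooled-variance Student's t by default
(matching the field's standard reporting) with Welch and paired variants
behind flags; exact p-values are always reported alongside the
tier labels (\* p < 0.05, \*\* p < 0.01, NS). Zero-variance degeneracies
are resolved explicitly (equal means → t=0, p=1; unequal → infinite-t
flag). Drug response is the per-experiment percent decrease
100·(pre − post)/pre — scale-invariant, positive for inhibition — and is
then summarised with its own mean ± SEM across experiments (a percent
change and the SEM of the underlying forces are different animals and
are never mixed). Day-by-condition aggregation pivots a tidy
per-experiment table; day/condition cells with n < 2 are reported
without a test. No multiple-testing correction is applied: the intended
use is a handful of planned comparisons.

## Numerical choices and degenerate inputs

* Sub-pixel localisation: intensity-weighted centroid (detection) and
  parabolic correlation-peak interpolation (tracking), both chosen over
  Gaussian fitting for robustness on flat-topped pillar images; the
  parabolic offset is clamped to ±1 px.
* Constant frames raise a degenerate-input error in detection; a
  featureless noisy frame returns an empty pillar set with a warning.
* All-lost trajectories and trajectories shorter than 10 frames are
  rejected by the reference estimators; < 4 or collinear centres are
  rejected by the lattice fit; < 2 beats yield an undefined-frequency
  flag; empty angle sets are rejected by the alignment summary.
* Simulation seeds are mandatory — there is no hidden global RNG state —
  and the pipeline records the seed, config hash and library versions in
  its manifest.

## Problem sizes

The standard synthetic recording used throughout the test-suite and the
reproduction script is a 5×5 lattice (25 pillars), 250 frames of
253×253 px (10 s at 25 fps), which renders in ~1 s and analyses in ~10 s;
unit tests use a 3×3 / 5 s variant. These sizes were chosen so the full
validation cycle runs in about a minute while still exercising every
stage at realistic pillar counts per field of view.

## Known limitations

* The beam model is linear; deflections approaching a substantial
  fraction of the pillar length would need large-deflection corrections.
* Tracking assumes in-plane motion and static pillar appearance; focus
  drift or z-motion will degrade correlation quality (visible in the
  `quality` column) rather than being corrected.
* The simulator's clean, symmetric blobs make sub-pixel accuracy easier
  than textured real pillar tops; real-data accuracy should be verified
  against fiducials or AFM-calibrated stiffness where possible.
* Beat segmentation assumes beats are separated by sub-threshold
  relaxation; fused tetanic-like activity is reported as single long
  events.
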