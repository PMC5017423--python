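# pillarbeat

Quantifying cardiomyocyte contractility from micropillar-array video.

Cardiomyocytes cultured on arrays of soft, vertical PDMS micropillars grip
the pillar tops and bend them with every beat. Because a slender elastomer
pillar is an excellent linear spring, the tip deflection read off a
microscope video is a direct force gauge: track the pillar top, and you
have measured the cell's twitch force — per pillar, per beat, with its
direction. `pillarbeat` implements that whole measurement chain for
anyone running pillar-based contractility or drug-response assays:

1. **Mechanics** — the Euler–Bernoulli cantilever stiffness of a
   circular-section pillar,

   $$k = \frac{3\pi E D^4}{64 L^3},$$

   with diameter $D$, length $L$ and Young's modulus $E$; a deflection
   $d = X_i - X_\mathrm{ref}$ of the pillar top from its relaxed position
   then converts to force as $F = k\,d$ (conveniently,
   $1\,\mu\mathrm{m}\times 1\,\mathrm{N/m} = 1\,\mu\mathrm{N}$). For the
   reference device — $D = 16\,\mu$m, $L = 48\,\mu$m, $E = 0.5$ MPa —
   this gives $k \approx 0.04$ N/m.
2. **Detection & tracking** — pillar tops are found by band-pass blob
   detection with sub-pixel centroid refinement, then followed through the
   stack by normalised cross-correlation template matching with parabolic
   sub-pixel peak interpolation (noise-free tracking error well below
   0.1 px).
3. **Beat analysis** — prominence-based peak segmentation of the
   deflection magnitude $d(t)$ yields per-beat amplitude, peak force,
   timing and direction; direction sets are summarised with circular
   statistics, including the axial order parameter
   $R_2 = \lvert\langle e^{2i\theta}\rangle\rvert$ that captures uniaxial
   (groove-aligned) beating even though contraction and relaxation point
   180° apart.
4. **Group statistics** — mean ± SEM per condition, Student's *t*
   comparisons (\* p < 0.05, \*\* p < 0.01), day-by-day aggregation and
   normalised drug-response (percent decrease) tables.
5. **Simulator** — a synthetic video generator that renders a beating
   pillar lattice (twitch waveform, direction field, PSF blur, sensor
   noise) with exact ground truth, so every stage above is validated
   against known answers.

## Worked example

```python
from pillarbeat import (PillarGeometry, ElasticMaterial, spring_constant,
                        default_fixture, run_pipeline)

k = spring_constant(PillarGeometry(16, 48), ElasticMaterial(0.5))
print(f"spring constant k = {k.n_per_m:.4f} N/m")

# synthetic 5x5 pillar lattice, 1 Hz / 3 um beating along 90 deg,
# 10 s at 25 fps, signal-to-noise ~ 10
stack, truth = default_fixture(seed=1, noise_sd=180.0)
result = run_pipeline(stack)
s = result.summary
print(f"pillars detected : {result.manifest['n_pillars']}")
print(f"beats found      : {s['n_beats_total']}")
print(f"beat frequency   : {s['median_beat_frequency_hz']:.2f} Hz")
print(f"mean amplitude   : {s['mean_beat_amplitude_um']:.3f} um")
print(f"mean peak force  : {s['mean_peak_force_un']:.4f} uN")
a = s['alignment']
print(f"axial order R2   : {a['axial_r2']:.3f} on axis {a['dominant_axis_deg']:.1f} deg")
```

prints

```
spring constant k = 0.0436 N/m
pillars detected : 25
beats found      : 250
beat frequency   : 1.00 Hz
mean amplitude   : 3.023 um
mean peak force  : 0.1319 uN
axial order R2   : 1.000 on axis 90.0 deg
```

All 25 pillars of the simulated lattice are recovered with 10 beats each;
the 3 µm / 1 Hz twitch programmed into the simulator is recovered to
better than 1% despite the noise, and the beating is perfectly uniaxial
along the programmed 90° axis ($R_2 = 1$). The mean peak force is the
recovered amplitude times the configured spring constant.

The same pipeline runs from the shell on any multi-page TIFF:

```sh
pillarbeat springconst -d 16 -l 48 -e 0.5
pillarbeat simulate --rows 5 --cols 5 --noise-sd 180 --seed 1 --out sim/
pillarbeat run --stack sim/stack.tif --out results/
pillarbeat compare --table experiments.csv --metric max_displacement_um --out stats.csv
```

`run` writes `pillars.csv`, `tracks.csv` (per-frame positions,
deflections and forces), `beats.csv`, an alignment summary and a manifest
carrying the config hash and versions, so reruns are reproducible
byte-for-byte.

## Documentation

See `docs/methods.md` for the model assumptions, the coordinate and unit
conventions, simulator design, numerical choices and known limitations.
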