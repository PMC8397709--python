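# isletwave

Analysis of intravital Ca²⁺ imaging recordings of pancreatic islets:
five-level activity classification, Ca²⁺ wavefront velocity, and
Pearson-correlation β-cell connectivity — plus a ground-truthed synthetic
recording generator so the whole pipeline runs and validates without animal
data.

## Who this is for

Labs doing longitudinal islet imaging (e.g. islets engrafted in the anterior
chamber of the eye, expressing GCaMP6f, imaged at 3 frames/s for 400-frame
captures) who want a reproducible, tested implementation of the standard
readouts:

- **Activity level 0–4** per capture: 0 no activity, 1 oscillations (Ca²⁺
  rises that do not advance across the islet), 2 partial wave, 3 whole-islet
  wave, 4 superwave (recurrent whole-islet wave). Classification works on
  per-cell onset times (half-maximum crossings of ΔF/F₀) and the three
  ordered islet regions (distal/middle/proximal) drawn along the wave axis.
- **Wavefront velocity** v = d/Δt (µm/s) between first- and last-recruited
  reference points.
- **Connectivity**: pairwise Pearson R between all smoothed cell-trace pairs
  over a 100-frame (~30 s) window, excluding the autocorrelation; pairs
  significantly connected by a circular-shift permutation test (or a fixed R
  threshold); % connected pairs, % connected cells and mean positive R;
  Cartesian connectivity maps with the standard colour bins (blue 0.1–0.25,
  green 0.26–0.5, yellow 0.51–0.75, red 0.76–1.0) and hub-cell highlighting;
  week-0 baseline correction of longitudinal metrics; two-group unpaired
  t-test plumbing.

See `docs/methods.md` for the models, conventions and limitations.

## Worked example

```python
import isletwave as iw

# a 24-cell islet (60 um radius) and a noiseless whole-islet wave at 50 um/s
geometry = iw.make_islet_geometry(24, islet_radius=60.0, min_spacing=12.0, seed=7)
params = iw.SimulationParams(level=3, wave_velocity=50.0, noise_sd=0.05, seed=11)
recording, truth = iw.simulate_recording(geometry, params)

cls = iw.classify_recording(recording, geometry)
print(cls.level, [e.kind for e in cls.events], [round(v, 1) for v in cls.velocities])

smoothed = iw.smooth_traces(recording)           # 5% rolling average, w = 21
corr = iw.pairwise_pearson(smoothed, 0, 100)     # 100-frame window
conn = iw.significant_pairs(corr, smoothed)      # circular-shift permutation
print(round(conn.pct_connected_pairs, 1), round(conn.mean_positive_r, 2))
```

prints

```
3 ['full'] [50.3]
94.9 0.68
```

i.e. the capture is classified level 3 (one full wave), the recovered
wavefront velocity is 50.3 µm/s (truth: 50), and — because every cell rides
the same wave — 94.9% of cell pairs are significantly connected with a mean
positive R of 0.68.

The same steps are available as a CLI
(`isletwave simulate | extract | classify | connect | report | pipeline`);
`isletwave pipeline --seed 0 --out-dir out/` runs a fully synthetic
longitudinal cohort (sham vs VSG, weeks 0/4/8/10) end to end and writes the
level time-course table, per-islet metrics with baseline correction, group
t-tests and a machine-readable `report.json`.

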