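# retstim

Quantifies the visual stimulation of the retina from head-mounted
eye-tracker recordings, comparing tasks such as reading and walking:

- **gaze-contingent luminance statistics** — RMS contrast and luminance
  skewness of gaze-centered samples, across space (per frame) and time
  (per retinal location), for the fovea (5° disc), the peripheral ring
  (8–60°, with upper/lower splits) and circular apertures of 5–60°;
- **visuomotor events** — piecewise-linear gaze segmentation with
  four-state classification (fixation / saccade / smooth pursuit /
  postsaccadic oscillation), fixation and saccade metrics;
- **blink detection** — a small convolutional eyes-open/eyes-closed
  classifier (pure NumPy, no deep-learning framework needed), blink
  events, durations, and 15-s-window rates;
- **head–eye dynamics** — high-velocity head events (2.5 × directional
  median threshold), event-triggered eye averages, head-pitch
  oscillation frequency;
- **optic flow / OKN** — dense optical flow by local polynomial
  expansion (coarse-to-fine, 5 scales × 10 iterations), average
  horizontal scene flow, turn-peak detection and optokinetic-nystagmus
  segment analysis (2–6 Hz Fourier band);
- **distribution fits** — Gaussian and Alpha-function least-squares
  fits, retinal illuminance in trolands, radially averaged spatial
  spectra, and a two-tailed Wilcoxon comparison utility;
- **synthetic sessions** — deterministic reading and walking session
  generators (scene video + gaze/pupil/IMU streams at 25/50/100 Hz in a
  vendor-style directory layout) with full ground truth, used by the
  test suite in place of non-deposited recordings.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (equation
oracles, worked troland/sampling-density computations, sign-structure
reproduction on fixed-seed synthetic sessions, flow and classifier
recovery bounds).

## CLI

```sh
retstim simulate --task reading --seed 1 --duration 60 --out sess/
retstim analyze  --session sess/ --out report/
retstim compare  --a sessA/ --b sessB/ --metric fovea.C_S
retstim blinks   --train --model model.npz --epochs 10
retstim okn      --session sess/
```

`analyze` writes per-frame/per-offset CSVs, a region × metric summary
table, interval/saccade/blink tables and a provenance record; config
can be supplied as JSON via `--config` (see
`retstim.pipeline.PipelineConfig`).

## Layout

```
src/retstim/
  session_io.py       session data model, directory reader/writer, geometry
  retinal_sampling.py retinal regions, offset sampling, luminance matrices
  scene_statistics.py contrast/skewness/spectra/trolands/fits
  eye_movement.py     segmentation + four-state classification
  blink.py            CNN open/closed classifier + blink events
  head_eye.py         head events, triggered averages, pitch frequency
  optic_flow.py       polynomial-expansion flow, turn peaks, OKN analysis
  synthetic.py        reading/walking session generators + ground truth
  pipeline.py         end-to-end orchestration, Wilcoxon comparisons
  cli.py              click-based command-line interface
```
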