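# diatrack

Markerless diaphragm-surrogate tumor tracking for rotational dual-kV
imaging during arc radiotherapy.

The package implements the full estimation chain on synthetic data:

1. **phantom** — seeded generator for a respiratory surrogate signal
   (sin^2n waveform with drift, cardiac pulsation, noise and irregularity
   events), coupled diaphragm-apex / tumor / fiducial-marker trajectories
   with controllable phase-dependent asynchrony and hysteresis, rendered
   dual-view projection frames (768×1024 px, 0.2 mm isocenter pixel size)
   and an angle-indexed 299×199 diaphragm template bank on a 0.3° grid.
2. **geometry** — stereo projection model for two orthogonal kV imagers on
   a rotating gantry: forward projection, ray back-projection, skew-ray
   midpoint triangulation, epipolar lines, lateral-region classification
   (50°–130° and 230°–310°).
3. **imaging** — preprocessing (marker inpainting from a 5–10 px annulus,
   log transform + density inversion, 75×205 downsample with bilinear
   restore) and exhaustive zero-mean normalized cross-correlation matching
   in windows anchored on the previous frame (±10 px horizontal, ±50 px
   vertical) or on the epipolar line of the paired view (±15 px) in the
   lateral region; dual-view tracking with per-frame triangulation.
4. **motion** — breathing-extrema detection, the three offset-vector
   scenarios (`S_no`, `S_con`, `S_var` with a phase-interpolated offset
   linear in the surrogate signal) and the quadratic correlation model
   `F(p) = a p² + b p + c + d ṗ² + e ṗ` fitted by closed-form least
   squares on a 20 s training window and applied over a 50 s evaluation
   window.
5. **evaluation** — signed mean±SD, E90/E95 percentile errors of absolute
   values, 3D norms, reduction ratio `R = 1 − E/A`, asynchrony residual,
   surrogate–tumor Pearson correlations.
6. **pipeline** — end-to-end session orchestration (simulate → render →
   track → model → predict → evaluate), CSV/JSON artifacts, YAML/JSON
   configuration; fully reproducible from (config, seed).

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds one test per acceptance criterion; the
full 351-frame dual-view tracked session is computed once in a shared
fixture (a few minutes on one CPU) and reused.

## CLI

```sh
# full pipeline on the synthetic phantom, all three scenarios
diatrack run-session --seed 7 --out results/session

# stages individually
diatrack simulate --seed 7 --out results/sim          # truth, signal, frames, templates
diatrack track --frames results/sim/frames --templates results/sim/templates \
               --out results/detections.csv
diatrack model --signal results/sim/signal.csv --apex apex.csv \
               --tumor tumor.csv --scenario S_var --out results/model.json
diatrack predict --model results/model.json --signal results/sim/signal.csv \
                 --out results/pred.csv
diatrack evaluate --pred results/pred.csv --truth results/sim/truth.csv \
                  --out results/eval.json
```

Session configs are YAML/JSON (see `diatrack.pipeline.SessionConfig`);
`--seed` overrides the config seed everywhere.

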