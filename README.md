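# gluimg

Analysis pipelines for two-photon movies of a surface-displayed fluorescent
glutamate sensor, covering two experiment types:

- **Slice (in situ) experiments** — an agonist is puffed repeatedly onto a
  sensor-expressing astrocyte while a red tracer marks each delivery. The
  pipeline scores stimulus-locked responses on a spatial grid, intersects the
  drug response map with a bath-glutamate positive-control map, labels
  release hotspots and classifies the cell as a responder.
- **Awake-mouse (in vivo) experiments** — spontaneous and stimulus-evoked
  events are counted per ROI after rigid motion gating. The pipeline
  segments up to 50 active ROIs, band-passes their traces, detects peaks,
  and calls the cell a responder from an area rule plus a paired
  signed-rank test on per-ROI peak frequencies.

A deterministic synthetic-movie generator with full ground truth supports
testing, calibration and end-to-end benchmarking without any raw data.

## Command line

```bash
# write a synthetic fixture set (movies + ground truth + manifest)
gluimg simulate --scenario responder --seed 0 -o fixtures/

# denoise / smooth / dF-F0 / z-score a two-channel movie
gluimg preprocess --green g.tif --red r.tif --pixel-size-um 0.293 -o out/

# slice analysis: drug acquisition + glutamate positive control
gluimg insitu-analyze \
  --green drug_green.tif --red drug_red.tif \
  --lglut-green lglut_green.tif --lglut-red lglut_red.tif \
  --pixel-size-um 0.293 -o results/

# awake-mouse analysis
gluimg invivo-analyze --green g.tif --red r.tif --stim-onset-s 15 -o results/

# summarise a finished run
gluimg report --results results/
```

Exit codes: `0` success, `1` usage/parameter error, `2` data error
(unreadable or inconsistent inputs, onset/motion estimation failure),
`3` analysis refusal (empty positive control, too few ROIs for the paired
test, unpairable acquisitions).

All parameters can be set in a YAML config (`--config run.yaml`); unknown
keys are rejected by name. `--print-config` echoes the fully resolved
configuration without running anything. Defaults live in
`gluimg.config.PARAMETER_DEFAULTS`.

## Python API

```python
from gluimg.synthetic import MovieSpec, generate_insitu_movie
from gluimg.preprocess import preprocess_stack, PreprocessParams
from gluimg.insitu import run_insitu_pipeline
from gluimg.invivo import run_invivo_pipeline

sim = generate_insitu_movie(MovieSpec(seed=1))
params = PreprocessParams(enable_nlm=False)
z = {k: preprocess_stack(s, params).z for k, s in {
    "dg": sim.drug.green, "dr": sim.drug.red,
    "lg": sim.lglut.green, "lr": sim.lglut.red}.items()}
out = run_insitu_pipeline(z["dg"], z["dr"], z["lg"], z["lr"],
                          pixel_size_um=0.293)
print(out["result"].responder, out["result"].responding_fraction)
```

See `docs/methods.md` for every analysis convention (windows, thresholds,
statistics) and the rationale behind the non-obvious choices.

## Tests

```bash
python -m pytest -q
```

The suite combines example-based tests, property-based tests (hypothesis)
and independent oracle re-implementations (naive loop scoring, flood-fill
labelling, analytic filter transfer, closed-form tail probabilities).
`tests/test_acceptance.py` holds one test per published acceptance
criterion, including two end-to-end classification panels on synthetic
ground truth.

The two printed acceptance targets are produced by:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which reports `t4` (mean 10–90% rise time of 20 noiseless simulated events,
in ms) and `t6` (ROI count returned by the default segmentation on a
60-region default movie).
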