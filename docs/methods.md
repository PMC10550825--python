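# Analysis methods and conventions

This document states every convention the pipelines implement, in enough
detail to reproduce any number the package prints. Parameter names refer to
`gluimg.config.PARAMETER_DEFAULTS`.

## Acquisition model

Movies are two-channel `(t, y, x)` stacks sampled every 30 ms
(`frame_period_ms`). Slice acquisitions default to 128×128 px at
0.293 µm/px for 120 s (4,000 frames); awake-mouse acquisitions default to
1.18 µm/px for 60 s. The green channel carries the glutamate sensor; the
red channel carries either the co-puffed tracer (slice) or a static
morphology marker (awake).

## Preprocessing (`gluimg.preprocess`)

Applied per channel, in order:

1. **Min–max normalisation** of the whole stack to [0, 1].
2. **Non-local-means denoising**, per frame (patch size 2, patch distance 4,
   h = 0.8). Skippable (`--no-nlm`) — it is the slowest stage and is not
   load-bearing for high-amplitude events.
3. **Gaussian smoothing**, σ = 0.5 in x, y and t (reflect boundaries).
4. **ΔF/F₀** per pixel with F₀ the per-pixel temporal mean. Pixels with
   |F₀| below 10⁻⁶ are flagged invalid and zeroed.
5. **z-scoring** per pixel over the whole acquisition, population SD
   (ddof = 0). Constant pixels are flagged and zeroed.

All "2z"-style thresholds below refer to these per-pixel z units.

## Slice pipeline (`gluimg.insitu`)

- **Puff onsets** — frames at which the FOV-mean red z-trace first reaches
  1z (`onset_threshold_z`), with a 10 s refractory period (half the 20 s
  puff interval) suppressing re-triggering on the slow tracer decay. The
  detector requires exactly the expected puff count (default 6) and raises
  otherwise — silent recovery from a wrong count would corrupt every epoch
  downstream.
- **Grid** — square 4-px cells (`grid_cell_px`, ≈1.4 µm² at the default
  pixel size); residual edge pixels are cropped.
- **Epoch scoring** — a cell responds in an epoch when the mean z-trace of
  its member pixels reaches ≥ 2z (`response_threshold_z`) within the
  post-onset window: frames `onset+1 … onset+8` (240 ms,
  `drug_window_frames`) for agonist puffs, 2 s (`lglut_window_s`) for the
  bath-glutamate positive control, whose responses are slower.
- **Reliability** — a cell is reliably responsive when it responds in ≥ 4
  of 6 agonist epochs (`min_green_responses`) and the tracer confirms
  delivery in **all** epochs. Motion-flagged cells can be excluded by mask.
- **Responding fraction** — |drug map ∩ control map| / |control map|. An
  empty control map is a refusal (`MissingControlError`), not a zero: it
  means sensor function was never demonstrated.
- **Hotspots** — 8-connected components of ≥ 4 cells
  (`min_hotspot_size`) in the intersection map.
- **Responder rule** — responding fraction ≥ 0.05 (`responder_threshold`,
  inclusive).

## Awake pipeline (`gluimg.invivo`)

- **Motion estimation** — each red frame is normalised by its mean,
  smoothed (σ = 3), thresholded at 1.2× mean intensity
  (`motion_contrast_threshold`, valid range [1.0, 1.5]) and matched by
  normalised cross-correlation against the time-averaged template (cropped
  by a 12 px search margin). Frames displaced more than 5 px
  (`max_shift_px`) on either axis are dropped; kept frames are shifted back
  by the negated integer offset. All later times are measured on the
  kept-frame timeline.
- **Activity map** — per-pixel `(max − median) / (1.4826 · MAD)` of the
  z stack. A plain z-maximum would be self-defeating: pixels with frequent
  events have event-inflated temporal SDs, which caps their z peaks near
  `1/√duty-cycle` and ranks busy pixels *below* quiet ones. The robust
  scale estimates the noise floor instead.
- **ROI segmentation** — the binarisation threshold is scanned from the map
  maximum down to the 0.80 quantile; the **lowest** threshold still
  yielding ≥ 50 (`n_max_rois`) components of ≥ 5 px (`min_roi_pixels`)
  is selected, so each ROI covers its whole contiguous active region rather
  than only its brightest core (the area-based responder rule below would
  otherwise be unreachable by construction). Components are ranked by peak
  activity; the top 50 are kept.
- **Traces** — mean over member pixels, re-standardised per trace, then
  ideal (brick-wall FFT) band-pass keeping periods of 150 ms – 2 s
  (`min_event_ms`, `max_event_ms`); receptor-blocker analyses use
  500 ms – 10 s.
- **Peaks** — after band-passing, traces are re-standardised by the robust
  median/MAD scale (a plain SD is inflated by the events themselves) and
  local maxima > 2z (`amp_threshold_z`) are kept when their width at half
  prominence exceeds 250 ms (`min_fwhm_ms`). Half-prominence width equals
  the classical FWHM for an isolated pulse on a flat baseline and stays
  well defined on a band-passed (zero-mean, oscillating) baseline, where an
  absolute half-maximum crossing systematically under-measures duration.
- **Per-ROI response** — peak frequency in the effect window must exceed
  the baseline-window frequency by > 25% (`min_frequency_increase`); a
  silent baseline with ≥ 1 stimulus-window peak counts as responsive.
- **Cell-level rule** — baseline window = first 10 s before the stimulus;
  effect window = the 10 s post-stimulus span (stepped in 5 s increments)
  maximising the mean peak frequency across ROIs. Responder iff
  (a) responsive ROIs cover ≥ 3% of the FOV (`area_threshold`), and
  (b) the per-ROI frequency change is significant by a paired two-sided
  Wilcoxon signed-rank test (p < 0.05, `alpha`) with a positive median
  change. Fewer than 6 ROIs is a refusal — the signed-rank test has no
  rejection region below that. *Caveat:* choosing the maximal-effect window
  and testing the same data is a scan statistic; its null rejection rate
  exceeds the nominal α (the coarse 5 s step bounds the inflation). The
  blocker comparison below uses fixed windows and is calibrated.
- **Cross-acquisition hotspots** — responsive ROI masks from two
  acquisitions are blurred (σ = 1), re-binarised at half maximum, and an
  ROI pair overlaps when the blurred masks share a pixel; the overlap
  fraction is reported over the smaller set.
- **Blocker comparison** — paired two-sided Wilcoxon signed-rank on matched
  per-ROI peak frequencies from two fixed periods. Identical frequencies
  give p = 1; unmatched ROI sets are a refusal (`PairingError`).

## Synthetic movies (`gluimg.synthetic`)

Events are a linear rise over `rise_ms / 0.8` (so the 10–90% rise time is
exactly `rise_ms` = 100 ms) followed by an exponential decay with
τ = `decay_ms` = 450 ms; the kernel peaks at exactly 1 on a sampled frame
and extends ≥ 5τ. Slice simulations place disjoint hotspots (with a
one-cell moat) responding per puff with configurable probability and
amplitude; awake simulations place disjoint active regions firing as a
piecewise-homogeneous Poisson process whose rate is multiplied after the
stimulus onset. Event trains are drawn from one kernel-length *before*
t = 0 so the process is stationary at the start of the acquisition —
without this burn-in the baseline window systematically under-counts and
biases the paired test. Rigid jitter and optional large (> 5 px) motion
frames displace both channels; noise is Gaussian (optionally Poisson) with
all intensities clipped to ≥ 0. Every generated quantity (onsets, event
times, masks, motion trace, responder flag) is returned as ground truth,
and fixture sets round-trip through TIFF/CSV/JSON with SHA-256 manifests.

## Determinism and refusals

A single integer seed determines every simulated fixture bit-for-bit.
Pipelines refuse (exit code 3) rather than guess when an analysis is
undefined: empty positive control, fewer than 6 ROIs, unpairable blocker
acquisitions. Wrong-looking inputs (onset count mismatch, featureless
motion template, malformed stacks) are data errors (exit code 2).
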