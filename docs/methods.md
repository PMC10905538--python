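# Methods

## The assay and its statistical model

A trap-array cytotoxicity assay discretizes an NK–tumor coculture into
hundreds of independent micro-experiments. Each hydrodynamic trap holds at
most one tumor cell and 0–3 NK cells at a fixed grid position, so a trap
defines a stable region of interest across a 24-h, 20-min-interval
time-lapse (73 frames: t = 0 plus 72 intervals). Treating each trap as a
subject and each NK-mediated tumor apoptosis (first persistent
caspase-3/7 signal over the tumor cell) as an event yields a standard
right-censored survival dataset per effector:target population
(1:0 and 0:1 controls, 1:1, 2:1, 3:1).

Survivability is the Kaplan–Meier product-limit estimate
S(t) = ∏ (nᵢ − dᵢ)/nᵢ over distinct event times tᵢ ≤ t, where nᵢ is the
risk set entering tᵢ and dᵢ the events at tᵢ. Censoring occurs only at the
horizon (status 2 = no event by 24 h), so S(24 h) = survivors/n₀ exactly —
a useful arithmetic cross-check against published summary tables (e.g.
261/263 = 0.9924). Censored observations leave the risk set but are never
counted as events; this is the convention consistent with that arithmetic.

Experimental populations are normalized against the on-chip tumor-only
control, S_norm(t) = (S_exp(t) − min S_cont)/(max S_cont − min S_cont),
to absorb background on-chip death. When the control has no deaths the
denominator is zero; the experimental curve is then returned unchanged
with a `degenerate_control` flag, since there is no background to remove.
Normalized values can leave [0, 1] when the experimental curve drops below
the control minimum; they are reported as-is with a warning.

Two-group comparisons use the standard log-rank statistic with
hypergeometric variance and a χ²(1) reference. A cell line is a
*responder* when its (duplicate-pooled) 1:1 24-h survivability is strictly
below 0.75; the threshold is a config knob (0.75 and 0.80 give the same
partition on the packaged reference data).

## Synthetic data generator

`simchip` emulates the study conditions: a rows×columns trap grid (30×29 =
870 traps in the standard device; composite split devices like
15×30 + 15×31 = 915 are supported), a small broken fraction, stochastic
occupancy (Bernoulli tumor cell, categorical 0–3 NK count), per-population
exponential death hazards, caspase signal onset at the event time, global
stage drift, and Gaussian sensor noise. Defaults: p(tumor) = 0.75, NK count
probabilities (0.25, 0.45, 0.20, 0.10), hazards 0.002/h for the tumor-only
control and 0.02–0.04/h for 1:1–3:1, noise σ = 80 counts against ~2500-count
trap walls and ~8000-count cells, drift (0.25, 0.1) px/frame, jitter 1 px.
The hazard model is exponential because it is the simplest death process
that permits closed-form recovery checks (S(24) = e^(−24λ)); occupancy and
hazard values are chosen to reproduce realistic population splits (most
traps 1:1, few 3:1) and 24-h survivabilities in the 0.4–1.0 range seen in
such assays. Event times are snapped *up* to the next frame time because
the pipeline can only observe state at frame times; the unsnapped times
are retained in the ground truth for distributional tests.

Rendering scale: the package's default geometry is a reduced-magnification
view — 28×36 px traps on a 42×56 px pitch, putting a 30×29 device on a
~1330×1700 px canvas — so that full-device, 73-frame simulations render and
analyze in about a minute. The native stitched-image scale (56×72 px traps,
a 30×29 grid filling ~3796×4641 px) is available via
`simchip.full_scale_geometry()`; all pipeline stages are
geometry-parameterized, and the 56×72 px crop convention is kept as the
default crop size. `LazyStack` renders frames on demand so full devices
never require the whole stack in memory.

What the generator does **not** emulate: optics (no point-spread function,
no channel cross-talk), cell migration within or between traps, NK-cell
apoptosis (config toggle exists but is off; only tumor deaths enter the
survival statistics), trap-wall deformation, illumination gradients, and
focus drift. Passing tests on synthetic data therefore demonstrate the
correctness of the accounting, tracking, calling and statistical machinery
under the stated noise model — not robustness to every real-microscopy
artifact. The detector is deliberately a pluggable contract so a learned
backend can replace template matching for real imagery.

## Numerical and design choices

- **Detection**: normalized cross-correlation against a rendered trap
  template, peaks above score 0.8, greedy NMS at IoU 0.3 (ties: higher
  score, then smaller (y, x)). On synthetic frames true traps score ≈0.99
  and spurious offsets ≈0.55, so the threshold sits in a wide margin.
- **Grid indexing**: y-centers are gap-clustered into rows (boundary =
  gap > half the estimated row pitch, with a minimum gap of 0.6× the
  median box height so single rows are never split); ids are row-major,
  sorted by x within a row. Deterministic and permutation-invariant.
- **Tracking**: nearest-centroid association gated at 5 px/frame, closest
  pairs first; no new tracks after frame 0; a miss leaves a gap and marks
  the track incomplete, but the track keeps competing in later frames so
  a single dropout does not cascade.
- **Census**: each fluorescent channel is counted independently
  (Laplacian-of-Gaussian blobs by default, circular Hough optional) inside
  a central 36×46 px window — crops are wider than the trap pitch, so
  counting the full crop would pick up neighbors. Channels whose maximum
  is < 1000 counts over background are treated as empty. The E:T label is
  assigned from frame 0 only and assumed constant.
- **Death calling**: tumor mask from the t₀ tumor channel; a frame is
  positive when ≥ 30% of the mask exceeds the caspase threshold
  (1500 counts); an event needs 2 consecutive positive frames (flicker
  suppression), except that a positive run truncated by the end of the
  series counts — persistence is unobservable past the final frame.
- **Survival**: curve evaluation at t uses the last step time ≤ t; the
  24-h read therefore tolerates horizons that are not exactly 24 h.
  Pooling duplicate runs re-keys traps by (run_id, trap_id) and refuses
  duplicate run_ids, which would silently double-count.
- **Panel ranking**: two-sided Wilcoxon rank-sum with Benjamini–Hochberg
  adjustment across panel genes, ranked by |Δ median| then adjusted p.
  The test choice is this package's addition for reproducible ranking;
  the source comparisons were qualitative.

## Problem sizes used in the shipped checks

Full-device detection checks use the complete 30×29 × 73-frame geometry.
End-to-end hazard-recovery runs use a 15×14 grid (~200 usable traps), the
log-rank type-I calibration uses 500 replicate event-table simulations at
n = 200 per group, the permutation reference uses 1000 permutations at
n = 40, and the brute-force product-limit oracle covers exhaustive status
patterns on small grids plus random tables up to n = 20. The published
24-h survivabilities are recomputed from event tables reconstructed from
the packaged experiment-overview marginals (see `tidi.reference`; the
reconstruction is synthetic and exact only at the horizon).

## Known limitations

- The reconstruction in `tidi.reference` fixes S(24) but not the interior
  curve shape; within-horizon comparisons (e.g. median survival) against
  the published curves are not meaningful.
- One experiment-overview entry (HN8, 3:1) is stored as missing because
  the printed value is unusable; HN8's 2:1 value is printed with truncated
  precision.
- Template matching assumes rigid, near-identical traps; heavily deformed
  or occluded traps would need the learned-detector backend.
- The log-rank p-value is asymptotic; for very small populations the
  permutation approach used in the tests is preferable.
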