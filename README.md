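# tidi

Analysis toolkit for **tumor–immune discretized interaction (TIDI)** assays:
microfluidic devices whose hydrodynamic traps immobilize one tumor cell with
0–3 natural-killer (NK) effector cells, imaged in four confocal channels
(brightfield, tumor tracker, NK tracker, caspase-3/7 apoptosis reporter)
every 20 minutes for 24 hours. Each trap is one micro-experiment at a known
effector:target (E:T) ratio; each NK-mediated tumor apoptosis is one event.
Hundreds of traps per device turn a coculture movie into a survival-analysis
dataset, letting patient-derived tumor lines be stratified by their
susceptibility to NK killing and joined to single-cell expression of NK
receptor–ligand genes.

The package is for lab scientists and image analysts running trap-array
cytotoxicity screens — and for anyone who wants a fully synthetic,
ground-truthed replica of such a screen to validate their analysis code.

## What it computes

1. **simchip** — synthetic chip time-lapses with exact ground truth: trap-grid
   geometry, stochastic occupancy, per-population exponential death hazards
   (times snapped up to the 20-min frame grid), 4-channel rendering with
   stage drift and noise.
2. **trapfind** — trap detection (normalized cross-correlation + NMS),
   row-major grid indexing, nearest-centroid tracking, whole-series
   completeness filtering, and 56×72 px per-trap crops. The crop dataset
   size obeys `|dataset| = (complete traps) × (timepoints)`.
3. **cytometry** — per-trap cell counting at t₀ (blob/circular-Hough per
   fluorescent channel), E:T population assignment (1:0, 0:1, 1:1, 2:1,
   3:1, other/empty), and caspase-based death-event calling with a
   persistence filter; output is a per-trap event table
   (status 1 = death event, 2 = no event).
4. **survival** — Kaplan–Meier product-limit estimation per population

   S(t) = ∏_{t_i ≤ t} (n_i − d_i) / n_i

   with censoring at the 24-h horizon, duplicate-run pooling, control
   normalization
   `S_norm(t) = (S_exp(t) − min S_cont) / (max S_cont − min S_cont)`,
   two-group log-rank testing, and responder classification
   (responder ⇔ S(24 h) at E:T = 1:1 below 0.75).
5. **ligandpanel** — a packaged 22-entry NK-92 receptor–ligand panel
   (11 inhibiting, 10 activating, 1 both) summarized per response group on
   an annotated expression matrix, with rank-sum + Benjamini–Hochberg
   ranking of group differences.
6. **pipeline / cli** — one YAML config drives
   `tidi simulate|detect|cytometry|survive|panel|all`, with a JSON manifest
   (parameters, output hashes, versions) per run.

## Worked example

A 10×10 synthetic device, 73 frames, hazards 0.03/h for 1:1 traps and
0.002/h for the tumor-only control:

```python
from tidi.pipeline import RunConfig, run_all

cfg = RunConfig(out_dir="demo", rows=10, cols=10, seed=7,
                hazards={"0:1": 0.002, "1:1": 0.03, "2:1": 0.045,
                         "3:1": 0.06, "1:0": 0.0, "other/empty": 0.002})
manifest = run_all(cfg)
```

prints (via the manifest):

```
simulate:  {'n_traps': 100, 'n_intact': 98}
detect:    {'n_tracks': 98, 'n_complete': 98}
cytometry: {'1:0': 10, '0:1': 20, '1:1': 36, '2:1': 21, '3:1': 7,
            'other/empty': 4}
survive:   {'s24_1to1': 0.5278, 'response': 'responder',
            'normalized_s24': {'1:1': 0.528, '2:1': 0.238, '3:1': 0.143},
            'logrank_1to1_vs_control_p': 0.00041}
```

All 98 intact traps were detected and tracked through all 73 frames; the
t₀ census partitioned them into the five E:T populations plus
"other/empty". The measured 1:1 24-h survivability 0.528 sits within
sampling error of the configured exp(−0.03·24) = 0.487 (36 traps), the
line is called a responder (< 0.75), and the log-rank test separates the
1:1 population from the tumor-only control at p ≈ 4×10⁻⁴.

`tidi.reference` ships the published per-run experiment overview for the
ten HNSCC lines (HN1–HN10) and reconstructs per-trap event tables from its
marginals (labelled synthetic; with end-censoring only, S(24) =
survivors/n₀ regardless of event-time placement), so the published 24-h
survivabilities — e.g. HN9 1:1 = 0.9924 over 263 traps, pooled HN5 1:1 =
0.3439 over 221 — and the responder partition {HN5, HN10} are recomputable
without any download.

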