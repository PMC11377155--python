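# inclutrack

Automated longitudinal single-cell survival tracking of α-synuclein
inclusion-bearing neurons in two-channel fluorescence time-lapse imaging —
detection, tracking, live/dead calling, Kaplan–Meier survival statistics,
inclusion subtype classification, and CRISPR-screen / MYTH interaction hit
calling, all exercisable against a bundled synthetic movie generator with
per-cell ground truth.

## Who this is for

Neurodegeneration labs that run long-term live imaging of induced neurons
(RFP-sparse-labeled, GFP-tagged α-synuclein; imaging every 6 h for 10 days
at 10X, ~0.8 μm/px) and need a tested, scriptable re-implementation of the
intensity-gate tracking algorithms used in that setting, including all
three published parameter sets:

- **seeded** — PFF-seeded inclusion model: GFP cell bodies (mean > 60,
  bounding-box sides 6–30 px), the per-cell "flexible" inclusion threshold
  (soma mean + 70), inclusion-positive at area ratio > 0.015, a secondary
  filter (ratio < 0.4 and mean GFP < 150) against bright rounded dying
  cells, RFP cell bodies (> 250, 10–30 px) for inclusion-negative neurons,
  and neurite-type inclusion gates (20–30 px long with GFP > 80, or
  > 30 px with GFP > 60; population-based readout).
- **spontaneous** — GFP > 40 at 15–30 px, absolute inclusion gate (≥ 160),
  positive above ratio 0.02, RFP > 180 at 10–40 px.
- **survival_v2** — RFP-based detection with a 160 intensity threshold,
  heavy morphological opening (5 erosion/dilation cycles on the start
  frame, 4 after) to strip thin linear areas, and a node-count death
  criterion: a neuron whose count of attached thin linear objects
  (neurites) reaches 0 is dead.

Tracking follows the published rules: tentative IDs at the analysis start
frame, frame-to-frame matching by centroid distance and relative area /
mean-intensity change, deletion of merged tracks, retention only of tracks
observed ≥ 5 frames, contiguous renumbering. Death is called at the first
frame with an area drop to ≤ 50% of the previous frame, a mean intensity
strictly below the detection threshold, or zero nodes (survival_v2);
neurons alive at the last frame are right-censored. Survival curves are
product-limit (Kaplan–Meier) estimates with Greenwood standard errors;
group comparison is the two-group log-rank test.

The package also implements the downstream classification and screening
rules from the same study design: inclusion subtypes from marker
co-labeling (Type I lipid+/p62−, Type IIa lipid−/p62+, Type IIb
lipid−/p62−), nucleus-integrity scoring with the 60 μm² Hoechst gate,
CRISPR-screen hit thresholds (|log2FC| ≥ 1 and FDR ≤ 0.1; strict
enhancer/suppressor heatmap cutoffs), MYTH lenient/stringent replicate
call rules, and exact gene-set overlap algebra.

## Worked example

```python
from inclutrack import (SimConfig, DetectorParams, simulate_experiment,
                        kaplan_meier, log_rank)
from inclutrack.pipeline import run_survival_analysis

config = SimConfig(n_cells=50, n_frames=40, seed=7)   # 10 days at 6 h cadence
stack, truth = simulate_experiment(config)

tracks, records = run_survival_analysis(stack, DetectorParams.seeded())
pos = [r for r in records if r.group == "inclusion_positive"]
neg = [r for r in records if r.group == "inclusion_negative"]
print(f"tracked {len(records)} neurons: "
      f"{len(pos)} inclusion-positive, {len(neg)} inclusion-negative")

for name, group in (("inclusion-positive", pos), ("inclusion-negative", neg)):
    curve = kaplan_meier(group)
    print(f"{name}: S(234 h) = {curve.survival_at(234.0):.3f}, "
          f"{int(curve.n_events.sum())} deaths")

chi2, p = log_rank(records, "inclusion_positive", "inclusion_negative")
print(f"log-rank: chi-square = {chi2:.2f}, p = {p:.4f}")
```

prints

```
tracked 49 neurons: 24 inclusion-positive, 25 inclusion-negative
inclusion-positive: S(234 h) = 0.417, 14 deaths
inclusion-negative: S(234 h) = 0.920, 2 deaths
log-rank: chi-square = 14.19, p = 0.0002
```

The simulator planted a per-frame death hazard of 0.02 for
inclusion-bearing neurons and 0.005 for inclusion-free neurons; the
pipeline recovers the toxicity difference (survival 0.417 vs 0.920 at the
end of the 10-day movie) and the log-rank test rejects equality. One of
the 50 cells died before the 5-frame retention horizon and was discarded
by the tracking rule, exactly as a cell lost that early would be in the
real assay.

A command-line surface wraps the same functions:

```bash
inclutrack simulate --out movie --seed 7
inclutrack survive --stack movie/stack --mode seeded --out survival
inclutrack screen simulate --n-genes 1000 --out screen_sim
inclutrack myth-call --scores myth_scores.csv --mode stringent --out calls.csv
```

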