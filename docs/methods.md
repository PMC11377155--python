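# Methods

## The tracking model

The package treats a long-term live-imaging experiment as a per-frame
segmentation problem followed by a constrained assignment problem and a
right-censored time-to-event analysis.

**Segmentation.** Each frame of the detection channel is binarized by a
strict intensity threshold, then opened morphologically: `n` cumulative
erosions followed by `n` dilations with a 3×3 square element. We read the
published "n cycles of erosion and dilation" as cumulative (erode n times,
then dilate n times) rather than n interleaved erode–dilate pairs: a single
3×3 opening is idempotent, so the interleaved reading would make the
survival_v2 schedule (5 cycles on the start frame, 4 thereafter) a no-op,
whereas the cumulative reading removes linear structures up to ~2n px wide —
which is the stated purpose of that step (eliminating thin neurite areas
from the cell-body mask). The final mask is intersected with the thresholded
mask, so opening output is always a subset of the threshold output; tests
verify both the subset property and equality with an independent
shift-based pixel oracle. 8-connected components are measured; a component
is a cell body when its *mean* intensity on the detection channel strictly
exceeds the printed gate (the tracker elsewhere reasons about "cell body
mean intensity", so mean—not per-pixel max—is the consistent semantics) and,
where a mode defines them, both axis-aligned bounding-box sides lie
inclusively within the printed pixel range. Major/minor-axis length is a
plausible alternative reading of "length and width"; the bounding box is the
simplest and is what we ship.

**Boundary semantics** are literal everywhere: "greater than" / "above" /
"below" / "less than" are strict; "X or higher", "≤", "≥" are inclusive.
Every gate in the package is unit-tested at its boundary.

**Somatic inclusions.** Inclusion pixels inside a cell body are those at or
above the cell mean + 70 (seeded; recomputed per cell per frame from the
whole-soma mean — the source does not say whether inclusion pixels are
excluded from the mean, and the whole-soma choice is the simpler one) or at
or above an absolute 160 (spontaneous). A cell is inclusion-positive when
the inclusion/cell-body area ratio strictly exceeds 0.015 (seeded) or 0.02
(spontaneous). The seeded secondary filter keeps a tracked neuron for
survival analysis only while its ratio stays below 0.4 and its mean GFP
below 150 (both strict); in the pipeline the filter is applied to whole
tracks using the per-track maxima, so a cell that ever enters the
bright-rounded regime is excluded, matching the filter's purpose.

**Neurite-type inclusions** are connected components of the GFP threshold
that do not overlap any cell body. Their "length" is the geodesic length of
the component's skeleton: the skeleton pixel graph (8-connected, step
weights 1 and √2) is swept twice with Dijkstra to get its diameter. For the
thin, nearly straight objects this readout targets, the skeleton is a path
and the measure is exact; the simulator renders segments along 45°-multiple
directions, for which geodesic and Euclidean endpoint length coincide, so
gate semantics are unambiguous in tests. Classification: short-and-thick at
20–30 px (inclusive) with mean GFP > 80, long above 30 px with mean GFP
> 60. The readout is population-based — a per-frame sum of lengths per
well, converted to μm at 0.8 μm/px — because neuritic inclusions cannot be
reliably assigned to a soma over time.

**Node counting (survival_v2).** The neurite mask is
`open(threshold(smooth(image)))` with a 3×3 mean filter. The default
threshold (150) sits between the smoothed response of a rendered neurite
(a 3-px line at ~350 counts smooths to ~240 at its core) and the smoothing
halo just outside a soma boundary (≤ ~170 at corner pixels, and the
single opening cycle removes what remains). Nodes of a cell are the
components of the neurite mask, after removing a 3-px collar around the
cell body, that reach the 2-px ring just outside the collar. The collar is
wider than the 1-px touch radius one might first write down because the
opened cell-body mask is a strict subset of the raw soma pixels: the
leftover boundary slivers would otherwise fragment into spurious
"touching" components. With the collar, node counts on simulated cells
recover the planted neurite counts exactly.

**Matching and tracks.** A previous/next region pair is admissible when
centroid displacement ≤ 15 px, |Δarea|/area ≤ 0.5 and |Δmean|/mean ≤ 0.5
(all configurable; the published description names the three criteria but
no values, and these pass simulator recovery while rejecting cross-cell
jumps on fields whose cells sit ≥ 2 gate radii apart). The assignment
minimizes, greedily in ascending order with ties to the lower previous
tentative ID, the symmetric normalized cost
`(d/15)² + (|Δarea|/area)² + (|Δmean|/mean)²`. Greedy equals the exhaustive
minimum-cost assignment on 1,000 random instances drawn from the tracking
regime (well-separated cells, small jitter); adversarial cost tables where
greedy is suboptimal exist but require inter-cell spacing the gates
already forbid. Tracks seed only from the analysis start frame, end at
their first unmatched frame (no gap closing — none is described, and the
tolerance is configurable), are deleted outright when two or more cells
are distance-admissible only to the same coalesced region, are discarded
under 5 observed frames, and are renumbered contiguously.

**Death calling.** First frame with area ≤ 50% of the previous frame
(inclusive), mean intensity strictly below the mode's detection threshold,
or (survival_v2) zero nodes. A retained track that vanishes from detection
before the movie ends is dead at its first missing frame: a sub-threshold
cell produces no detection, so disappearance *is* the intensity-collapse
criterion in practice — with the default matching gates, a dying cell's
60% area drop also exceeds the area-change gate, so simulated deaths
surface through this path at exactly the planted frame. Whether the
intensity criterion references the detection gate or a separate value in
the seeded/spontaneous variants is not specified at the source;
the detection gate is used and exposed as a parameter (survival_v2
specifies 160). Death is absorbing; a cell alive on the last frame is
censored there.

**Survival statistics.** Times are hours from the analysis start frame
(frame index × 6 h; absolute days-in-vitro are metadata, not part of the
axis). Kaplan–Meier and the two-group log-rank test are computed with
lifelines; deaths precede censorings at tied times (the standard
convention). Greenwood standard errors are attached to each curve. Tests
check the estimator against an independent risk-set enumeration oracle on
randomized small datasets.

## The synthetic experiment

The generator's defaults are the study conditions: 512×512 px fields at
0.8 μm/px, 40 frames at 6 h (10 days), ~50 adherent neurons per field with
1 px/frame Gaussian positional jitter, soma diameters 16–24 px, GFP soma
means 80–135 and RFP means 300–450 over a background of 20 with additive
Gaussian noise (σ = 3) — intensities placed inside the printed gate ranges
so the published thresholds apply without rescaling, since the original
intensity units are instrument-specific (the camera is 12-bit; frames are
written as 16-bit TIFF, the common container). Half the cells carry a
somatic inclusion rendered 100 counts above the soma mean over 8% of the
soma area. Death is a per-frame Bernoulli hazard (0.02 with inclusion,
0.005 without); a dying cell renders once at ≤ 40% of its previous area
(with a half-pixel radius margin so the discretized disk respects the
bound) and disappears thereafter. Optional layers: elongating
neurite-type inclusion segments (2 px/frame growth, capped at 80 px, kept
clear of somata), per-cell neurites in RFP for node counting (driven to 0
at death), marker channels (LIPID/P62/HOECHST) with planted subtype labels
drawn at Type I 12.5%, IIa 60%, IIb 25%, mixed 2.5% — near the reported
seeded-model frequencies — and intact (radius 6 px ≈ 72 μm²) versus
fragmented (three 2-px fragments ≈ 8 μm² each) nuclei around the 60 μm²
gate.

What the simulator deliberately omits: point-spread blur (thresholds are
raw-intensity gates), photobleaching, stage drift, tile stitching, cell
migration and division, overlapping or touching cells, and autofluorescent
debris. Passing recovery tests therefore demonstrates that the gates,
matcher and death rules implement their definitions faithfully on data
that satisfies the algorithms' own assumptions — not that the pipeline is
robust to segmentation ambiguity in real micrographs, where the published
parameter values would still need per-instrument recalibration.

## Screens and interactions

The gene-level aggregator is deliberately *not* MAGeCK or edgeR (out of
scope); it is a documented stand-in producing the quantities the published
thresholds consume: median per-gRNA log2 fold change (pseudocount 1,
median-of-ratios library normalization, replicates averaged), a
permutation p-value from 1,000 re-draws of gene-sized gRNA sets out of the
pooled per-gRNA fold changes (independent draws per gene, chunked for
memory), and Benjamini–Hochberg FDR. The count simulator plants essential
genes (depleted in all genotypes, log2FC −2), 3K-specific enhancers
(−2 in 3K only) and suppressors (+1.5 in 3K only) in negative-binomial
counts (variance μ + 0.1μ², 500× mean depth, 5 gRNAs/gene) — a
genome-scale screen distilled to the features the thresholds act on.
Recovery runs at 800 genes rather than 18,166: the hit logic is per-gene,
so the smaller table tests the same code path at a desk-scale problem
size. MYTH calls and the set-overlap arithmetic are exact rule
implementations with exhaustive truth-table tests.

## Evaluation conventions

- **Death-call accuracy** is measured over planted deaths at or after
  frame 5: the 5-frame retention rule makes earlier deaths definitionally
  untrackable (in the original pipeline as well), so they are outside the
  algorithm's design envelope rather than errors.
- **Hazard recovery** conditions on survival to frame 4 (left truncation)
  for the same reason: retained tracks are death-free on frames 1–4 by
  construction, and counting that immortal time as exposure would bias the
  per-frame hazard estimate low. With truncation, the pooled estimate over
  ≥ 500 tracks covers the configured hazard within its exact binomial 95%
  CI.
- **Log-rank calibration** (type-I error within [0.03, 0.07] at n =
  100/group over 1,000 repetitions; power > 0.9 at hazard ratio 3) is
  simulated at the survival-record level with the same geometric death
  process the image simulator uses — the property under test concerns the
  statistic, not the renderer.

## Known limitations

- The detector assumes one neuron per connected component; touching cells
  are a single region and will be merge-deleted rather than resolved.
- Neurite "length" via skeleton geodesics slightly overestimates Euclidean
  length for lines off the 45° grid (≤ 8%, worst at arctan ½ slopes).
- The permutation null assumes a balanced design (equal gRNAs per gene);
  unbalanced tables fall back to a slower per-gene loop.
- Converter cells (lipid-positive inclusions turning lipid-negative) are
  simulated as a label switch at a configured frame; no transition model
  is fitted, matching the upstream-label treatment of that group.
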