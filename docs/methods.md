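# Methods

## Setting and scope

`phantomqa` analyzes phantom-based consistency tests of lesion-detection
AI for CT angiography. The measured object is the AI's *output* — 8-bit
RGB heatmap overlays and scan-level triage verdicts — never the AI
itself, which is treated as a black box. The reference experiment is an
anthropomorphic head phantom with three intracranial aneurysms (middle
cerebral artery and anterior communicating artery, 4 mm maximum diameter
each; basilar artery, 2 mm) scanned at 21 CTDIvol levels from 0.47 to
20.09 mGy at 120 kVp, reconstructed with both iterative reconstruction
(IR) and filtered back projection (FBP), three repetitions per cell: 126
scans, axial 512 × 512 matrix, 0.41 mm pixels, 0.75 mm slices. The tube
current–time product carries the dose variation (7–298 mAs); rotation
time is 0.3 s at the lowest dose and 0.5 s elsewhere.

## Label quantification

A pixel belongs to a label iff its blue-channel value is ≤ 100
(inclusive: the threshold is the *maximum* admissible blue value for a
label pixel). Positive pixels are grouped into maximal connected
components; the default is volumetric 26-connectivity, so one lesion's
label spanning slices is a single component, with per-slice 4- and
8-connectivity available.

Size is pixel count × pixel size. That phrase is dimensionally
ambiguous, so both readings are computed and recorded: the default
**area** convention (n·p², mm², the physically meaningful 2-D measure)
and the **literal linear** product (n·p). Intensity converts label RGB to
grayscale (BT.601 luma 0.299R + 0.587G + 0.114B in floating point; an
equal-weights mean is configurable), inverts and normalizes:
(255 − gray)/255, averaged over the component's pixels, giving a value
in [0, 1].

## Matching and triage

Human label review is replaced by geometry: component centroids are
assigned to lesion centroids by greedy nearest-distance one-to-one
matching, accepting pairs within 10 mm. Distances are anisotropic
(in-plane pixel size, through-plane slice thickness). The tolerance is a
declared parameter, chosen to accept the slightly offset labels that
occur at low dose while rejecting distant blobs; it is configurable.
Greedy order is (distance, lesion id, component id), which makes the
result deterministic and input-order invariant; on well-separated
configurations it coincides with the exhaustive minimum-total-distance
assignment (asserted in tests for up to 4 lesions). Because matching is
one-to-one, a lesion is never credited with two components; a split
label would leave its second fragment as a candidate false positive
(logged as a warning), a known limitation rather than a modeled case.

Triage is independent of matching: any component at all ⇒ positive
heatmap; none ⇒ negative summary report. The phantom is lesion-positive
by construction, so scan-level positives are true positives and
negatives are false negatives.

## Consistency metrics

Counts of matched labels are tabulated per lesion × dose ×
reconstruction (each cell in [0, repetitions]) with completeness checked
against the design. Rates are 100 · count/total, reported at full
precision and rounded to one decimal in formatted output.

Reproducibility uses the coefficient of variation (sample SD over mean;
n−1 denominator, configurable to population SD) of label size and
intensity, restricted to cells in which **every** repetition produced a
matched label — a cell missing a repeat confounds detection failure with
measurement variability. Two poolings are reported because either is
defensible and the choice matters: the default computes a CV within each
qualifying dose (across its 3 repeats) and averages those CVs across
qualifying doses, isolating repeat-to-repeat variability from the dose
trend; the pooled mode computes one CV over all contributing values and
therefore includes dose-driven size changes. Lesion × reconstruction
pairs with no qualifying cell are flagged not-computable (NaN), never
zero.

## Reader arm

Readers rate visibility (yes/no; 1 = yes, 2 = no also accepted at
ingest) and image quality (3/2/1) per lesion and scan. Quality ratings
of 1 are recoded to 0 when the reader also rated the lesion invisible —
"poor but visible" and "not assessable" are distinct outcomes. Quality
is aggregated as a two-stage mean: within reader across a cell's
repetitions, then across readers; the error bar is the SEM across
readers (not across repeats). On a balanced design the two-stage mean
equals the flat mean (asserted as a property test).

## Statistics

Group comparisons (between lesions within a reconstruction, or between
reconstructions within a lesion) use the two-sided Mann–Whitney U test.
The unit of analysis is the per-cell mean across repeats — one value per
dose — so repeated acquisitions never enter as independent observations;
with 21 doses each group has up to 21 units (fewer for lesions with
unmatched cells, which are absent, not zero). Exact permutation p-values
are used when the pooled sample is ≤ 20 without ties; otherwise the
normal approximation with mid-ranks, tie correction and continuity
correction (an explicit request for the exact test with ties falls back
with a warning, since exact enumeration is not valid under ties).
Bonferroni adjustment min(1, m·p) is applied within each family of
pairwise comparisons (m = family size, allowed to exceed the number of
p-values supplied); significance is α = 0.05 after adjustment.

## Synthetic study generator

The generator reproduces the *statistical structure* of the experiment,
not its physics: no CT noise texture, reconstruction kernels, or
anatomy. Heatmaps are standalone overlays, which is sufficient because
the analysis consumes only overlay pixels and geometry.

Per scan and lesion, detection is a Bernoulli draw with probability
σ(β₀ + β₁ ln d) — a logistic in log-dose — optionally multiplied by
1 − a·σ(s·ln(d/k)) to model a reconstruction whose labeling degrades
above a knee dose k (the qualitative FBP behavior). Default parameters
were fixed once to emulate the reference study's structure: MCA
(β₀, β₁) = (3, 8) for IR and (2.5, 8) for FBP (labeled almost always,
except at the lowest dose); ACoA (−4.5, 3) with a mid-dose threshold
near 4.5 mGy, plus FBP degradation (amplitude 0.35, knee 14 mGy,
steepness 3); BA a flat logit of −3 (IR, ≈ 5%) and −5 (FBP, ≈ 0.7%).
These yield expected per-reconstruction label counts close to the
reference counts (≈ 60/57 MCA, ≈ 46/39 ACoA, ≈ 3/0.4 BA per 63 scans).

Detected labels are rendered as filled in-plane discs in a hot color
(red 255; green/blue shrink with color depth, blue always ≤ 90) on a
neutral background (230, 230, 230), so the blue-threshold rule separates
label from background exactly. Disc radius is (max diameter)/2 scaled by
the saturating factor d/(d + 1 mGy), a per-lesion-and-reconstruction
size scale (MCA 1.0, ACoA 0.7, BA 0.8 — conspicuous lesions draw larger
labels), and lognormal jitter (σ = 0.10, giving area CVs around 0.2).
Color depth follows the same saturating form with its own scale (MCA
1.0, ACoA 0.8, BA 0.7) and Gaussian jitter (σ = 0.05). Label centres are
offset isotropically in-plane with 2 mm Gaussian scale, emulating the
slightly offset low-dose labels; sub-pixel discs light the nearest
pixel, and a disc entirely outside the image is a generation error. A
disc's blue value never exceeds the threshold, and background never
falls below it, so segmentation recovers rendered labels exactly
(asserted as a round-trip test).

The reader model draws visibility from σ(a₀ + a₁ ln d + bᵣ) per lesion
with small per-reader biases bᵣ ∈ {−0.4 … 0.4}, and quality from a
cumulative-logit model in log-dose (forced to 1 when invisible).
Defaults give near-ceiling visibility that degrades only at the lowest
doses (overall ≈ 99% MCA, ≈ 99% ACoA, ≈ 94% BA) and quality that
improves with dose, with MCA rated above the other two and ACoA ≈ BA.

All randomness flows from one top-level seed through named substreams
keyed by scan id (and reader id), hashed into the seed sequence. Adding
doses, repetitions, or readers therefore never perturbs existing scans'
draws, and identical seeds give bit-identical pixels and tables.

What passing tests on synthetic data do *not* show: that a real AI's
failures follow a logistic in log-dose, that real labels are discs or
have uniform color, or that real CV magnitudes match the defaults. The
generator exists to validate the analysis machinery (calibration,
conservation, restriction rules, determinism), not to predict any
vendor's behavior.

## Numerical and design choices

- Problem sizes: the reference design uses 8-slice 512 × 512 stacks,
  processed as a stream (one scan's pixels in memory at a time).
  Calibration checks use 2 000 truth-only scans (no rendering) and the
  logistic-recovery check 50 repetitions per cell at the 21 reference
  doses.
- Provenance: every output carries the seed, tool version and a SHA-256
  config hash; wall-clock timestamps are deliberately excluded so that
  identical configurations produce byte-identical output trees.
- Rounding: rates to one decimal and CVs to two decimals in formatted
  report fields; full precision always retained alongside in CSV/JSON.
- Degenerate inputs: empty components are unrepresentable; empty masks
  yield empty component lists; cells without matches yield absent (NaN)
  summaries; CV without qualifying cells is flagged, not zeroed; rate
  denominators of zero are errors.
- Ties in matching are broken by lesion id, then component id,
  lexicographically.
- The DICOM RGB secondary-capture dialect is best-effort (reading
  requires Photometric Interpretation RGB and takes geometry from
  PixelSpacing/SliceThickness); the PNG-stack tree is the reference
  format.

## Known limitations

- Geometric matching stands in for expert label review; a grossly
  mislocalized but visually correct label would be scored unmatched.
- The false-positive pathway is minimal: unmatched components are
  flagged and counted, but vessel-occlusion-style alerts from other
  algorithms are out of scope.
- The comparison families default to lesion-pairwise within
  reconstruction and reconstruction-pairwise within lesion on per-cell
  means; other groupings must be declared by the user.
- Reader idiosyncrasy is modeled only as an additive bias; individual
  reader–scan interactions are not simulated.
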