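# Methods

This note documents the models, conventions and design decisions behind
`neuroquant`, and what the synthetic-data tests do and do not establish
about real data.

## Fluorescence index and ratio

For a single-channel image with integer intensities, the index is the
histogram-weighted sum `Σ_b c(b)·b²`, equal by construction to the
per-pixel sum of squared brightness. It is computed from the full
integer histogram (one bin per level, 256 or 65,536) with 64-bit integer
accumulation, so the histogram route and the per-pixel route agree
*exactly* at both bit depths; there is no floating-point tolerance in
this statistic. Useful exact properties follow: `index(c·I) = c²·index(I)`
for an unsaturated image, and the index is additive over any disjoint
tiling.

Conventions:

* **Raw intensities.** No rescaling to [0, 1] and no background
  subtraction before indexing. Background is handled experimentally by
  the secondary-antibody-only negative control, so the index operates on
  raw histogram bins. Both channels of a pair must share dimensions and
  bit depth; the marker/DAPI ratio is then scale-consistent and
  dimensionless.
* **Saturation.** Saturated pixels are included in the index; a field
  with more than 1% saturated pixels raises a quality warning because
  the squared statistic is biased downward at the detector ceiling.
* **Color images are refused.** Channel identity (red/green = marker,
  blue = DAPI) is semantic; a caller must extract a named channel
  explicitly rather than rely on implicit grayscale conversion.
* **Undefined ratios.** A field whose DAPI channel is all zero has no
  cells; the ratio is an explicit error, and batch quantification flags
  the row instead of dropping it, so output row counts always equal
  input pair counts.
* **Replicate structure.** Technical replicates are averaged within
  each biological replicate before any group test (the study design this
  serves images two biological × two technical repeats per condition);
  this avoids pseudo-replication.
* **Tests.** Stained-vs-control detection uses a *one-sided* Welch test
  (specific staining can only add signal); condition contrasts (e.g.
  passage 5 vs 25) use the *two-sided* test with Welch–Satterthwaite
  degrees of freedom and stars at 0.05/0.01/0.001. Degenerate inputs
  follow explicit conventions: identical zero-variance groups give
  t = 0, p = 1; groups with a single observation report the mean
  difference with no p-value.

## qPCR: −ΔΔCt and reference stability

Perfect amplification efficiency (factor 2.00 per cycle) is assumed; no
standard-curve correction is applied. Technical replicates are averaged
first to one Ct per (gene, biological sample); the technical sd is
retained (it is the error bar of a per-replicate plot) alongside the
biological sd of −ΔΔCt. The normaliser is the arithmetic mean of the
reference-gene Ct values — equivalent to the geometric mean of their
linear quantities, the geNorm convention. Then per sample
`ΔCt = Ct_target − mean(Ct_refs)`, and `ΔΔCt` is the group-mean ΔCt
minus the calibrator-group mean. Both −ΔΔCt (log2 fold change) and
2^(−ΔΔCt) (fold change) are emitted, since published bar plots are
ambiguous between the two scales.

A global additive Ct shift on all genes of a sample (loading/pipetting
effect) cancels in ΔCt exactly in exact arithmetic; the test suite
verifies bit-identical invariance on Ct values quantised to 1/1024 of a
cycle with power-of-two replicate counts, where every intermediate mean
is exactly representable.

Reference stability uses the classic pairwise-variation measure: for
candidate j, `M_j = mean_{k≠j} sd_samples(log2 q_j/q_k)` on quantities
`q = 2^(−Ct)`, so the per-sample log-ratio is simply `Ct_k − Ct_j`; sd
uses ddof = 1. Partners are accumulated in a canonical (sorted) order so
the result is bitwise invariant to the candidate list's order. The
iterative gene-elimination procedure and the V(n/n+1) cutoff for
choosing how many references to keep are out of scope; the ranking alone
reproduces the "pick the two most stable of six candidates" decision.
Per-gene Welch stars carry no multiple-testing correction — a documented
limitation that mirrors common per-gene reporting practice.

## Single-cell QC

The filter is two single-pass stages on a genes × cells UMI matrix:

1. jointly on the raw matrix: keep genes detected in **≥ 3** cells and
   cells with **≥ 300** detected genes;
2. on surviving cells, with metrics computed on the **raw** matrix:
   keep cells with **< 15,000** total UMIs and **< 10%** mitochondrial
   counts.

Boundary semantics are explicit and tested: exactly 300 features is
kept; exactly 15,000 UMIs or exactly 10.0% mitochondrial is removed.
Whether the UMI/mito stage should use raw or post-gene-filter metrics
is genuinely open; raw metrics were chosen because the rules read as
sequential selections on the loaded data, and the thresholds object
makes the convention switchable. Gene removal is deliberately *not*
iterated (a cell can end below 300 features after rare genes are
dropped); the contract is the single pass, and the report's arithmetic
(`before − removed = after` per rule, removals attributed to the first
failing rule in the order features → UMI → mito) is asserted instead.
The mitochondrial predicate is a case-insensitive `MT-` name prefix,
overridable by an explicit gene list. The 0/0 mitochondrial percentage
of an empty cell is defined as 0 — such a cell fails the feature rule
regardless.

Cluster summaries consume externally produced annotations (cluster ids,
cell-cycle phases from {G1, S, G2M}, lineage classes): phase occupancy
per cluster with a strict `frac_G1 > 0.80` dominance flag (exactly 80%
is not dominant; G1-dominant clusters are read as terminally
differentiating populations), and lineage composition ratios computed
from a user-supplied cluster→lineage map — the map is an input, never
hard-coded, because lineage assignment is a narrative judgement.

## Growth

`M = log2(n_grown / n_seeded)` per passage; negative M is a valid
observation (culture loss) and a zero harvest yields a −inf sentinel
with a `crashed` flag rather than an error, because real cultures crash.
The cumulative curve is a raw running sum — no smoothing — and is
additive under series concatenation.

## Synthetic data: what it emulates and what it does not

* **Images** emulate the geometry that gives the index a signal: nuclei
  as isotropic Gaussian blobs (centres rejection-sampled to ≥ 2σ apart),
  cytoplasmic marker staining as a 1.8σ footprint on a fixed fraction of
  cells, uniform background, optional Poisson shot noise and Gaussian
  read noise, clip-and-quantise to 8 or 16 bits. Defaults (16-bit,
  256×256, 40 nuclei of σ = 4 px, background 200, read noise 30) are
  stated choices for a mid-density field, not inferences from any
  instrument. Not emulated: realistic PSFs, uneven illumination,
  autofluorescence, staining heterogeneity within a cell, or touching
  nuclei — so passing ordering/calibration tests show the *estimator*
  responds correctly to planted signal, not that any specific microscope
  is calibrated.
* **Ct tables** use one cycle ≡ one doubling, Gaussian replicate noise
  (default 0.2 cycles), optional per-sample global shifts and per-gene
  instability jitter. Amplification-efficiency variation and melt-curve
  artefacts are not modelled.
* **UMI matrices** plant each violation class into cells that satisfy
  every other rule, and anchor all non-rare genes in ≥ 3 rule-passing
  cells, so ground-truth pass/fail labels are exact by construction.
  The count distributions are simplistic (uniform feature draws with a
  multinomial split) — adequate for testing a threshold filter, not for
  benchmarking normalisation or clustering.
* **Growth series** draw per-passage doublings around a constant rate;
  senescence and density dependence are not modelled.

Seeding: all generators derive their streams from a root seed through
`numpy.random.SeedSequence(seed, spawn_key=(k,))`, with a documented
child index per consumer (field geometry k=0, stained noise k=1,
control noise k=2), so a stained field and its negative control share
geometry but have independent noise, and any fixture can be regenerated
in isolation.

## Problem sizes in the test and acceptance runs

The suites run at desk scale by choice: 500 random images up to 48 px a
side for exact-equality checks, 20 simulation seeds per condition for
ordering tests, 100 simulations for power and −ΔΔCt recovery, 1,000 for
test size, 200 random matrices for filter equivalence, 40 seeds for the
stability ranking. These sizes give the statistical assertions
comfortable margins (e.g. binomial 95% bands) while keeping a full run
in seconds.

## Known limitations

* The index has no illumination-field or segmentation component; it is
  a whole-field statistic and inherits whole-field artefacts.
* Welch stars are per-comparison; families of contrasts need external
  correction.
* The QC filter intentionally reproduces loading-time semantics rather
  than iterating to a fixed point.
* CLI plotting is out of scope; outputs are tidy CSV/JSON for plotting
  elsewhere.
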