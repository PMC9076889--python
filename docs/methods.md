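# Methods

## The strand-bias statistic and its post-processing

Reads carrying Watson/Crick labels are assigned to fixed-width bins (5 kb
default) by their midpoint, tiled from coordinate 0 with 0-based half-open
intervals throughout. The per-bin statistic is `(W − C) / (W + C)`; bins
with fewer than 4 reads are masked, never zero-filled, and the mask is
carried by `numpy.ma` arrays so filtered bins cannot re-enter downstream
arithmetic. The coverage filter applies to the raw track only and is not
re-applied after smoothing.

**Control normalization.** The matched nascent-DNA (BrdU-IP) library is an
unbiased sample of both nascent strands, so its bias estimates the
strand-sampling asymmetry of the protocol. We normalize by per-bin
*subtraction* of the control bias: a ratio of signed quantities is
ill-defined near 0, where the control sits by construction, while
subtraction removes an additive asymmetry cleanly. The operator is
isolated in `normalize_bias` so an alternative transform can be swapped
in. Because a difference of two values in [−1, 1] can leave that range,
the result is clipped back to [−1, 1]; with a well-behaved control the
clip is inactive, and keeping the range invariant simplifies every
consumer.

**Smoothing.** "Flanking five bins" is read as five bins *per side*: an
11-bin centered moving mean, masked-aware (the mean is over the unmasked
values in the window), truncated at chromosome boundaries. A bin whose
window contains no unmasked value stays masked. The flank is a parameter
(`flank_bins`); 0 is the identity.

**Origin aggregation.** Bias values are collected at bin offsets within a
flank (default 40 kb, the pulse-replicated window) around each origin.
The per-origin matrix is ordered by descending firing efficiency — the
heatmap ranking; in real data that ranking would come from Okazaki-
fragment strand asymmetry, so the key is pluggable. Stored tracks are
never sign-flipped by side; the flip lives only inside
`leading_bias_score`, defined as ½(mean bias over right offsets − mean
bias over left offsets) across all unmasked matrix cells, with the center
bin excluded by default. Under the strand convention below, positive
scores mean leading-strand enrichment.

**Strand convention.** A single constant: the nascent leading strand of a
rightward-moving fork maps to the Watson (plus) strand. Hence
leading-enriched samples are Watson-biased right of origins and
Crick-biased left, giving the canonical antisymmetric profile orientation.

## Coverage normalizations

RPM scales every bin by `1e6 / total mapped reads`; spike-in scales by
`1e6 / human-aligned library size`. Both are exact linear maps, so bin
rank order is preserved and `scale_factor × library size = 1e6` is an
algebraic identity (exact in floating point whenever the division is).
Region means are length-weighted by fractional bin overlap — bins are
coarse relative to regions in toy data, and fractional overlap avoids edge
bias. Metagene profiles rescale each gene body to a fixed number of
segments (strand-aware, so profiles run TSS→TTS in the direction of
transcription) with fixed-bp flanks; the flank width and segment counts
are parameters since no canonical values exist for them. Correlation
matrices re-bin tracks by summation into 50 kb windows and drop, pairwise,
windows with zero coverage in either track. Expression quartiles are an
input column; no expression estimation is performed.

## Live-cell quantification

The input contract is a table of per-cell *integrated* signals — the
whole-nucleus summed intensity per frame, as produced upstream by
projection and segmentation; background handling is assumed done and is
not modeled here. Phase calling snaps times to the nearest frame (20 min
default), ties rounding toward mitosis. Offset mode uses
mitosis − 11 h / − 1 h / + 1 h (12 h for double mutants, which cycle more
slowly); geminin mode calls G1/S at the first crossing above 50% of the
trace maximum sustained ≥ 2 frames and mitosis at the first subsequent
drop below 25% (all thresholds exposed). Signals are normalized per cell
to the G1/S value, so re-normalizing an already normalized cohort is a
no-op. The group test is the classic equal-variance unpaired two-tailed
Student t (df = n₁ + n₂ − 2), the variant the name denotes; Welch is
available behind a flag. Degenerate zero-variance inputs return p = 1
when the means agree.

## What the simulator emulates — and what it does not

The simulator's defaults encode the study conditions the analyses assume:
a 40-minute nucleotide pulse; fork speed 1000 bp/min (so a fired origin
replicates ~40 kb per side during the pulse); 200 bp nucleosome spacing;
100 bp reads centered on the histone position; a 20% human spike-in
admixture with equal per-cell labeled-chromatin yield; imaging frames
every 20 min over a 16 h horizon. Origins fire as independent Bernoulli
trials per cell-equivalent with probability equal to their efficiency;
toy genomes place origins far enough apart that fork collisions need not
be modeled. Parental histones inside the replicated window are recycled
with probability `retain_prob` and land on the leading strand with
probability `p_leading`. Genotype presets (WT 0.55; Mcm2-2A/Pola1-2A
0.75; Pole3/Pole4 KO 0.40; double mutant 0.55, with reduced retention in
mutants) are free simulator knobs chosen to reproduce the qualitative
pathway ordering — no quantitative per-genotype transfer probabilities
exist to calibrate against, and these numbers must not be read as
biological estimates.

The bulk-coverage model treats the labeled parental pool per cell as
constant while chromatin content grows by `1 + f` with the replicated
fraction `f`, so the mouse read yield per cell dilutes as `1/(1 + f)` and
the expected human read share at `f` is `s / (s + (1 − s)/(1 + f))` —
exactly 20% at the baseline. Read positions follow a weight profile of 1
plus the gene's H3.3 weight inside gene bodies (weights 0.5/1/2/4 for
quartiles Q1–Q4), which makes quartile ordering in metagene profiles a
recoverable construction.

The live-cell model draws each cell's retained fraction binomially over
10,000 histone units, applies it geometrically across S phase, bleaches
continuously at `bleach_rate` per hour, and splits the mitotic signal by
a symmetric Beta(50, 50) fraction, with a one-ulp fix-up so the daughters'
float sum equals the mother's handed-off signal bit-exactly. Because
bleaching is continuous, the daughter sum read 1 h after mitosis trails
the G2 value read 1 h before by the factor `exp(−2β·1 h)`; it equals it
exactly when `bleach_rate = 0`. The geminin channel is a noisy 0/1 step —
high from G1/S to mitosis.

Not modeled: fragment-length and GC effects, sequencing errors, Okazaki
maturation, fork stalling, replication timing, origin interference, local
histone exchange during transcription, and image-level effects (the trace
is the input contract). Passing tests therefore certify the statistics
and their implementations, not the biology of real libraries: real eSPAN
data add mappability, copy-number and S-phase-heterogeneity structure
that the toy genome deliberately lacks.

## Numerical and design choices

* One root seed; per-assay child streams derived via `SeedSequence`, so
  fixed (config, seed) gives byte-identical outputs.
* Read-to-bin assignment by midpoint; a read belongs to exactly one bin.
* W = C = 0 bins are masked (not 0); masks propagate through
  normalization (union) and smoothing (empty-window).
* Origin efficiency is typed strictly positive, (0, 1]; a never-firing
  locus is represented by omitting the origin rather than by efficiency 0.
* Problem sizes used by the test suite and acceptance script — two 1 Mb
  chromosomes, 8 origins, 40 genes, 30–50 k reads per library, 100–200
  cells — were chosen as the smallest scale at which the Monte-Carlo
  checks (3-SE null bounds, 95% CI recovery) are comfortably stable.
* Plots are courtesy outputs; the numeric TSV/bedGraph files are the
  contract, and the manifest checksums cover only those.

## Known limitations

The double-mutant preset restores the WT bias *by construction* (both
pathways impaired symmetrically), so its near-WT score is a consistency
check of the pipeline, not evidence about the mechanism. The spike-in
model assumes human cells neither replicate nor lose label over the
chase. The geminin caller requires one rise and one fall per trace; cells
imaged mid-S-phase would need the thresholds retuned.
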