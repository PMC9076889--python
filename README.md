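# forkhist

Strand-resolved analysis of parental-histone inheritance at DNA replication
forks, for epigenomics groups studying replication-coupled histone
recycling (e.g. with SNAP-tagged H3.1/H3.3 in mouse ES cells).

When a replication fork passes, parental histones are recycled onto the two
nascent strands by replisome chaperones: the Mcm2–Pola1 axis hands them to
the lagging strand, Pole3–Pole4 to the leading strand. eSPAN (chromatin
profiling of labeled histones followed by BrdU immunoprecipitation of
nascent single-stranded DNA) makes that partition measurable: reads mapping
to the Watson (W, plus) and Crick (C, minus) strands are separated, and for
each genomic bin the strand bias is

    bias = (W − C) / (W + C)

computed in 5 kb bins, ignoring bins with fewer than 4 reads, normalized by
subtracting the bias of the matched BrdU-IP control library, and smoothed
with a 5-bin flank (11-bin window). Around a replication origin the leading
strand of the rightward fork is the Watson strand, so a leading-strand-
enriched sample gives an antisymmetric profile — negative left of the
origin, positive right — summarized by a scalar `leading_bias_score`.

The package also implements the two companion quantifications:

* **Spike-in coverage time-courses** — labeled-histone CUT&RUN densities
  scaled either to reads-per-million (RPM, factor `1e6 / total mapped
  reads`) or to a human spike-in admixture (factor `1e6 / human library
  size`), with region density tables, TSS→TTS metagene profiles split by
  expression quartile, and 50 kb-window Pearson correlation matrices.
  Under full retention, spike-in-normalized parental density follows
  `1/(1+f)` in the replicated fraction `f`, while RPM density is flat.
* **Live-cell inheritance quantification** — per-cell integrated-signal
  traces through one division, with cell-cycle points called at fixed
  offsets from mitosis (G1/S 11 h before, G2 1 h before, next G1 1 h
  after; 12 h for double mutants) or from a geminin reporter channel,
  signals normalized per cell to G1/S, and two-tailed unpaired Student
  t tests between groups.

Because the real measurements need deposited sequencing data, the package
ships a first-class simulator (`forkhist.genome`, `forkhist.simulate`)
that generates all three read-outs from known ground truth: bidirectional
forks from origins with stated efficiencies, a 40-minute pulse window,
tunable leading-strand deposition probability per genotype, an unbiased
nascent-DNA control, expression-weighted bulk coverage with a 20% human
spike-in, and mother/daughter signal traces with optional photobleaching
and recycling loss. Every analysis stage is therefore testable against
closed-form expectations without any download.

## Worked example

```python
import forkhist as fh
from forkhist.simulate import SimulationConfig, GENOTYPE_PRESETS

genome = fh.make_genome(2, 1_000_000, 8, 40, seed=7)
for gt in ("WT", "Mcm2-2A", "Pole4KO", "Mcm2-2A+Pole4KO"):
    cfg = SimulationConfig(seed=11, n_cells=32, n_reads=50_000)
    espan, brdu = fh.simulate_espan(genome, GENOTYPE_PRESETS[gt], cfg)
    b = fh.compute_bias(fh.count_stranded_reads(espan, genome))
    ctrl = fh.compute_bias(fh.count_stranded_reads(brdu, genome))
    smooth = fh.smooth_bias(fh.normalize_bias(b, ctrl))
    profile = fh.aggregate_origins(smooth, genome.origins, 40_000)
    print(f"{gt:18s} leading_bias_score = {fh.leading_bias_score(profile):+.3f}")
```

prints

```
WT                 leading_bias_score = +0.079
Mcm2-2A            leading_bias_score = +0.363
Pole4KO            leading_bias_score = -0.140
Mcm2-2A+Pole4KO    leading_bias_score = +0.077
```

WT shows the expected slight leading-strand tilt; breaking the
lagging-strand pathway (Mcm2-2A) pushes recycled histones onto leading
strands (score up), breaking the leading-strand pathway (Pole4 KO) tips
them the other way (score down), and the double mutant restores a roughly
WT balance — the qualitative signature of the two-pathway model.

Quantifying a simulated lossless live-cell cohort:

```python
traces = fh.simulate_live_cell(GENOTYPE_PRESETS["WT"], 100, seed=11)
calls = {t.cell_id: fh.call_phases(t) for t in traces if t.parent_id is None}
stats = fh.quantify_inheritance(traces, calls)
```

gives `g2_over_g1s = 1.000 ± 0.000`, `d1_over_g1s = 0.503 ± 0.049`,
`d2_over_g1s = 0.497 ± 0.049`, `daughters_over_g2 = 1.000 ± 0.000`
(n = 100): the parental pool is conserved through S phase and split
evenly between daughters, and `g1s_to_mitosis_duration` recovers
11.00 ± 0.00 h from the geminin channel.

## Command line

```bash
forkhist run-all --seed 1 --genotype Mcm2-2A --out-dir run1
forkhist simulate --seed 1 --out-dir sim1
forkhist espan-bias sim1/espan_reads.bed --genome-dir sim1/genome \
    --control sim1/brdu_reads.bed --out-dir bias1
forkhist live-cell run1/cell_traces.tsv --mode geminin
```

`run-all` executes simulate → count → bias → normalize → smooth →
aggregate plus the coverage time-course and live-cell stages, writing
plain-text outputs (BED6, bedGraph, TSV), courtesy PNG profiles, and a
`manifest.json` with the config hash and per-file checksums; identical
config and seed reproduce identical checksums.

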