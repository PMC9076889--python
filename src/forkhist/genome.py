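"""Toy genome construction for replication / histone-inheritance simulations.

A :class:`GenomeModel` is the coordinate frame shared by every downstream
stage: a handful of small chromosomes, replication origins with firing
efficiencies, gene models carrying expression quartiles and an H3.3
enrichment weight, and a set of H3.3-enriched regions. All coordinates are
0-based, half-open, in base pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Origin",
    "GeneModel",
    "GenomeModel",
    "GenomeCapacityError",
    "make_genome",
    "H33_WEIGHT_BY_QUARTILE",
]

# H3.3 is enriched at actively transcribed genes; the weight grows with the
# expression quartile (Q1 = lowest, Q4 = highest) and multiplies the baseline
# chromatin sampling weight inside gene bodies.
H33_WEIGHT_BY_QUARTILE: dict[int, float] = {1: 0.5, 2: 1.0, 3: 2.0, 4: 4.0}


class GenomeCapacityError(ValueError):
    """Requested origins/genes cannot be placed without overlap at the stated spacing."""


@dataclass(frozen=True, order=True)
class Origin:
    """A replication origin: bidirectional forks start here.

    ``efficiency`` is the probability that the origin fires in a given
    cell-equivalent, i.e. the fraction of cells in which it initiates.
    """

    chrom: str
    position: int
    efficiency: float

    def __post_init__(self) -> None:
        if not (0.0 < self.efficiency <= 1.0):
            raise ValueError(f"origin efficiency must be in (0, 1], got {self.efficiency}")
        if self.position < 0:
            raise ValueError(f"origin position must be >= 0, got {self.position}")


@dataclass(frozen=True)
class GeneModel:
    """A gene with expression quartile and H3.3 enrichment weight.

    ``tss`` and ``tts`` are stored as genomic coordinates with ``tss < tts``
    (left/right on the reference); for a minus-strand gene the biological
    transcription start lies at the ``tts`` coordinate and consumers that
    need orientation (metagene scaling) flip using ``strand``.
    """

    chrom: str
    tss: int
    tts: int
    strand: str
    quartile: int
    h33_weight: float

    def __post_init__(self) -> None:
        if self.tss >= self.tts:
            raise ValueError(f"gene requires tss < tts, got [{self.tss}, {self.tts})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be '+' or '-', got {self.strand!r}")
        if self.quartile not in (1, 2, 3, 4):
            raise ValueError(f"quartile must be 1..4, got {self.quartile}")
        if self.h33_weight < 0:
            raise ValueError("h33_weight must be nonnegative")

    @property
    def length(self) -> int:
        return self.tts - self.tss


@dataclass
class GenomeModel:
    chromosomes: list[tuple[str, int]] = field(default_factory=list)
    origins: list[Origin] = field(default_factory=list)
    genes: list[GeneModel] = field(default_factory=list)
    h33_regions: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def chrom_length(self, name: str) -> int:
        for cname, length in self.chromosomes:
            if cname == name:
                return length
        raise KeyError(f"unknown chromosome {name!r}")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def validate(self) -> None:
        lengths = dict(self.chromosomes)
        if len(lengths) != len(self.chromosomes):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length {length}")
        for o in self.origins:
            if o.chrom not in lengths:
                raise ValueError(f"origin on unknown chromosome {o.chrom!r}")
            if not (0 <= o.position < lengths[o.chrom]):
                raise ValueError(f"origin at {o.chrom}:{o.position} outside chromosome")
        order = [(o.chrom, o.position) for o in self.origins]
        if order != sorted(order):
            raise ValueError("origins must be sorted by (chrom, position)")
        for g in self.genes:
            if g.chrom not in lengths:
                raise ValueError(f"gene on unknown chromosome {g.chrom!r}")
            if not (0 <= g.tss < g.tts <= lengths[g.chrom]):
                raise ValueError(f"gene [{g.tss}, {g.tts}) outside {g.chrom}")
        for chrom, start, end in self.h33_regions:
            if chrom not in lengths or not (0 <= start < end <= lengths[chrom]):
                raise ValueError(f"H3.3 region {chrom}:{start}-{end} outside genome")


def _split_counts(total: int, n_parts: int) -> list[int]:
    base, rem = divmod(total, n_parts)
    return [base + (1 if i < rem else 0) for i in range(n_parts)]


def make_genome(
    n_chroms: int,
    chrom_length: int,
    n_origins: int,
    n_genes: int,
    seed: int,
    *,
    min_origin_spacing: int = 20_000,
    origin_margin: int = 50_000,
    gene_length_range: tuple[int, int] = (5_000, 20_000),
) -> GenomeModel:
    """Build a deterministic toy genome.

    Origins are spread evenly (with small jitter) across chromosomes, away
    from the ends by ``origin_margin``, and receive efficiencies spanning
    (0, 1] in a seed-shuffled order. Genes occupy non-overlapping slots and
    are assigned expression quartiles in equal proportion, with the H3.3
    weight increasing monotonically in quartile. H3.3-enriched regions are
    the (merged, 1 kb-padded) bodies of Q3/Q4 genes.

    Raises :class:`GenomeCapacityError` when origins or genes cannot be
    placed without overlap.
    """
    if n_chroms <= 0:
        raise ValueError("n_chroms must be >= 1")
    if chrom_length <= 0:
        raise ValueError("chrom_length must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x6E0]))
    chromosomes = [(f"chr{i + 1}", int(chrom_length)) for i in range(n_chroms)]

    # --- origins -----------------------------------------------------------
    origins: list[Origin] = []
    if n_origins > 0:
        margin = origin_margin if 2 * origin_margin < chrom_length else chrom_length // 10
        span = chrom_length - 2 * margin
        per_chrom = _split_counts(n_origins, n_chroms)
        for k in per_chrom:
            if k > 0 and span / k < min_origin_spacing:
                raise GenomeCapacityError(
                    f"cannot place {k} origins with spacing >= {min_origin_spacing} bp "
                    f"in a usable span of {span} bp"
                )
        if n_origins > 1:
            efficiencies = np.linspace(1.0, max(0.1, 1.0 / n_origins), n_origins)
        else:
            efficiencies = np.array([1.0])
        efficiencies = rng.permutation(efficiencies)
        i_eff = 0
        for (cname, _), k in zip(chromosomes, per_chrom):
            if k == 0:
                continue
            spacing = span / k
            for j in range(k):
                jitter = rng.uniform(-0.1, 0.1) * spacing
                pos = int(margin + (j + 0.5) * spacing + jitter)
                pos = min(max(pos, margin), chrom_length - margin - 1)
                origins.append(Origin(cname, pos, float(efficiencies[i_eff])))
                i_eff += 1
    origins.sort(key=lambda o: (o.chrom, o.position))

    # --- genes -------------------------------------------------------------
    genes: list[GeneModel] = []
    if n_genes > 0:
        lo, hi = gene_length_range
        per_chrom = _split_counts(n_genes, n_chroms)
        quartiles = rng.permutation(np.array(sum(([q] * c for q, c in
                                                  zip((1, 2, 3, 4), _split_counts(n_genes, 4))), [])))
        i_gene = 0
        for (cname, _), k in zip(chromosomes, per_chrom):
            if k == 0:
                continue
            slot = chrom_length // k
            if slot < lo + 1_000:
                raise GenomeCapacityError(
                    f"cannot place {k} non-overlapping genes of >= {lo} bp "
                    f"in slots of {slot} bp on {cname}"
                )
            for j in range(k):
                length = int(rng.integers(lo, min(hi, slot - 1_000) + 1))
                start = int(j * slot + rng.integers(500, slot - length - 500 + 1))
                strand = "+" if rng.random() < 0.5 else "-"
                q = int(quartiles[i_gene])
                genes.append(GeneModel(cname, start, start + length, strand, q,
                                       H33_WEIGHT_BY_QUARTILE[q]))
                i_gene += 1
    genes.sort(key=lambda g: (g.chrom, g.tss))

    # --- H3.3-enriched regions: padded Q3/Q4 gene bodies, merged ----------
    h33_regions: list[tuple[str, int, int]] = []
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        if g.quartile >= 3:
            start = max(0, g.tss - 1_000)
            end = min(chrom_length, g.tts + 1_000)
            by_chrom.setdefault(g.chrom, []).append((start, end))
    for cname in sorted(by_chrom):
        merged: list[list[int]] = []
        for start, end in sorted(by_chrom[cname]):
            if merged and start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append([start, end])
        h33_regions.extend((cname, s, e) for s, e in merged)

    return GenomeModel(chromosomes=chromosomes, origins=origins, genes=genes,
                       h33_regions=h33_regions)
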