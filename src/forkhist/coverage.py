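"""Normalized coverage analysis.

Two exact linear scalings of binned read counts — reads-per-million (RPM,
scale factor ``1e6 / total mapped reads``) and spike-in (scale factor
``1e6 / human-aligned library size``) — plus region density tables,
TSS->TTS metagene profiles split by expression quartile, and genome-wide
Pearson correlation matrices over coarse windows.

RPM normalization cancels global dilution of a constant labeled pool, so
RPM densities are flat across a chase time-course; spike-in normalization
preserves absolute abundance, so per-locus parental density follows
``1 / (1 + f)`` in the replicated fraction ``f``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GeneModel, GenomeModel
from .simulate import StrandedRead

__all__ = [
    "BinnedCounts",
    "DensityTrack",
    "MetageneProfile",
    "bin_reads",
    "rpm_normalize",
    "spikein_normalize",
    "metagene_profile",
    "region_density",
    "correlation_matrix",
]

DEFAULT_CORRELATION_WINDOW = 50_000  # bp


@dataclass
class BinnedCounts:
    """Raw per-bin read counts (strand-agnostic)."""

    bin_width: int
    data: dict[str, np.ndarray]

    @property
    def total(self) -> int:
        return int(sum(v.sum() for v in self.data.values()))


@dataclass
class DensityTrack:
    """Per-bin coverage under a named normalization.

    ``density = raw count * scale_factor`` in every bin. ``library_size``
    is the denominator the scale factor was derived from (total mapped
    reads for RPM, human-aligned reads for spike-in).
    """

    bin_width: int
    data: dict[str, np.ndarray]
    normalization: str
    scale_factor: float
    library_size: int
    human_library_size: int | None = None

    @property
    def chroms(self) -> list[str]:
        return list(self.data)


def bin_reads(
    reads: Iterable[StrandedRead],
    genome: GenomeModel,
    bin_width: int,
) -> BinnedCounts:
    """Tally reads into fixed-width bins by midpoint, tiled from 0."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lengths = genome.chrom_lengths
    data = {c: np.zeros(-(-l // bin_width), dtype=np.int64) for c, l in genome.chromosomes}
    for read in reads:
        if read.chrom not in lengths:
            raise ValueError(f"read on unknown chromosome {read.chrom!r}")
        mid = read.midpoint
        if 0 <= mid < lengths[read.chrom]:
            data[read.chrom][mid // bin_width] += 1
    return BinnedCounts(bin_width, data)


def _scaled(counts: BinnedCounts, factor: float) -> dict[str, np.ndarray]:
    return {c: v.astype(float) * factor for c, v in counts.data.items()}


def rpm_normalize(counts: BinnedCounts, total_mapped_reads: int) -> DensityTrack:
    """Reads-per-million: scale every bin by 1e6 / total mapped reads."""
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    factor = 1_000_000.0 / total_mapped_reads
    return DensityTrack(counts.bin_width, _scaled(counts, factor), "rpm",
                        factor, int(total_mapped_reads))


def spikein_normalize(counts: BinnedCounts, human_library_size: int) -> DensityTrack:
    """Spike-in scaling: scale every bin by 1e6 / human-aligned library size.

    The identity ``scale_factor * human_library_size == 1e6`` holds exactly.
    """
    if human_library_size <= 0:
        raise ValueError("human_library_size must be positive")
    factor = 1_000_000.0 / human_library_size
    return DensityTrack(counts.bin_width, _scaled(counts, factor), "spikein",
                        factor, int(human_library_size),
                        human_library_size=int(human_library_size))


def _interval_mean(values: np.ndarray, bin_width: int, start: float, end: float) -> float:
    """Length-weighted mean of a per-bin step function over [start, end)."""
    if end <= start:
        return float("nan")
    b0 = int(start // bin_width)
    b1 = int(-(-end // bin_width))
    b1 = min(b1, values.size)
    b0 = max(b0, 0)
    if b1 <= b0:
        return float("nan")
    edges = np.arange(b0, b1 + 1, dtype=float) * bin_width
    lo = np.maximum(edges[:-1], start)
    hi = np.minimum(edges[1:], end)
    overlap = np.clip(hi - lo, 0.0, None)
    total = overlap.sum()
    if total <= 0:
        return float("nan")
    return float((values[b0:b1] * overlap).sum() / total)


@dataclass
class MetageneProfile:
    """Mean density across scaled gene bodies plus fixed-bp flanks.

    ``positions`` runs upstream flank -> body (scaled) -> downstream flank
    in the transcriptional orientation; ``by_quartile`` maps quartile label
    (1..4) to the mean profile over its genes.
    """

    n_scaled_bins: int
    n_flank_bins: int
    flank_bp: int
    by_quartile: dict[int, np.ndarray]
    gene_counts: dict[int, int]
    n_excluded: int = 0

    @property
    def n_positions(self) -> int:
        return self.n_scaled_bins + 2 * self.n_flank_bins

    def body_slice(self) -> slice:
        return slice(self.n_flank_bins, self.n_flank_bins + self.n_scaled_bins)

    def mean_body_density(self, quartile: int) -> float:
        return float(np.nanmean(self.by_quartile[quartile][self.body_slice()]))


def metagene_profile(
    density: DensityTrack,
    genes: Sequence[GeneModel],
    n_scaled_bins: int = 60,
    flank_bp: int = 2_000,
    n_flank_bins: int = 20,
) -> MetageneProfile:
    """Average density over genes rescaled TSS->TTS, by expression quartile.

    Each gene body is rescaled to ``n_scaled_bins`` equal segments; flanks
    cover ``flank_bp`` in fixed bp split into ``n_flank_bins`` segments.
    Profiles are oriented in the direction of transcription (minus-strand
    genes are flipped). Genes shorter than one density bin are excluded and
    counted in ``n_excluded``.
    """
    if n_scaled_bins < 2:
        raise ValueError("n_scaled_bins must be >= 2")
    bw = density.bin_width
    profiles: dict[int, list[np.ndarray]] = {1: [], 2: [], 3: [], 4: []}
    n_excluded = 0
    for gene in genes:
        if gene.length < bw:
            n_excluded += 1
            continue
        values = density.data[gene.chrom]
        body_edges = np.linspace(gene.tss, gene.tts, n_scaled_bins + 1)
        up_edges = np.linspace(gene.tss - flank_bp, gene.tss, n_flank_bins + 1)
        down_edges = np.linspace(gene.tts, gene.tts + flank_bp, n_flank_bins + 1)
        segs = np.concatenate([up_edges[:-1], body_edges[:-1], down_edges])
        prof = np.array([
            _interval_mean(values, bw, segs[j], segs[j + 1])
            for j in range(segs.size - 1)
        ])
        if gene.strand == "-":
            prof = prof[::-1]
        profiles[gene.quartile].append(prof)

    by_quartile = {
        q: (np.nanmean(np.vstack(rows), axis=0) if rows
            else np.full(n_scaled_bins + 2 * n_flank_bins, np.nan))
        for q, rows in profiles.items()
    }
    gene_counts = {q: len(rows) for q, rows in profiles.items()}
    return MetageneProfile(n_scaled_bins, n_flank_bins, flank_bp, by_quartile,
                           gene_counts, n_excluded)


def region_density(
    density: DensityTrack,
    regions: Sequence[tuple[str, int, int]],
    region_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Length-weighted mean density per region.

    Returns a DataFrame with columns region_id, chrom, start, end,
    mean_density. Regions outside the genome raise an error naming the
    region.
    """
    ids = region_ids if region_ids is not None else [
        f"{c}:{s}-{e}" for c, s, e in regions
    ]
    rows = []
    for rid, (chrom, start, end) in zip(ids, regions):
        if chrom not in density.data:
            raise ValueError(f"region {rid} on unknown chromosome {chrom!r}")
        values = density.data[chrom]
        if not (0 <= start < end <= values.size * density.bin_width):
            raise ValueError(f"region {rid} outside genome bounds")
        rows.append((rid, chrom, start, end,
                     _interval_mean(values, density.bin_width, start, end)))
    return pd.DataFrame(rows, columns=["region_id", "chrom", "start", "end",
                                       "mean_density"])


def _rebin(track: DensityTrack, window_bp: int) -> np.ndarray:
    """Aggregate a track into window_bp windows by summation, concatenated."""
    factor = window_bp // track.bin_width
    if factor < 1 or window_bp % track.bin_width != 0:
        raise ValueError("window_bp must be a positive multiple of the track bin width")
    parts = []
    for chrom in track.chroms:
        v = track.data[chrom]
        n_win = -(-v.size // factor)
        padded = np.zeros(n_win * factor)
        padded[: v.size] = v
        parts.append(padded.reshape(n_win, factor).sum(axis=1))
    return np.concatenate(parts)


def correlation_matrix(
    tracks: Sequence[DensityTrack],
    window_bp: int = DEFAULT_CORRELATION_WINDOW,
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Pairwise Pearson r between tracks over coarse genome windows.

    Tracks are re-binned by summation into ``window_bp`` windows; for each
    pair, windows with zero coverage in either track are dropped before
    computing r. The diagonal is exactly 1.
    """
    if len(tracks) < 2:
        raise ValueError("need at least two tracks")
    bw = tracks[0].bin_width
    if any(t.bin_width != bw for t in tracks) or any(
        t.chroms != tracks[0].chroms for t in tracks
    ):
        raise ValueError("tracks must share bin width and chromosomes")
    names = list(labels) if labels is not None else [
        f"track{i}" for i in range(len(tracks))
    ]
    vectors = [_rebin(t, window_bp) for t in tracks]
    n = len(vectors)
    r = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            x, y = vectors[i], vectors[j]
            keep = (x != 0) & (y != 0)
            if keep.sum() < 2:
                raise ValueError(
                    f"fewer than 2 usable windows between {names[i]} and {names[j]}"
                )
            r[i, j] = r[j, i] = stats.pearsonr(x[keep], y[keep]).statistic
    return pd.DataFrame(r, index=names, columns=names)
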