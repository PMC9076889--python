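"""The eSPAN strand-bias core.

Reads carrying Watson/Crick labels are binned by midpoint, the per-bin bias

    bias = (W - C) / (W + C)

is computed genome-wide with low-coverage bins (fewer than ``min_reads``
reads) masked rather than zero-filled, the bias is normalized against the
matched nascent-DNA control by per-bin subtraction, smoothed by a
masked-aware centered window, and aggregated around replication origins
into mean profiles and efficiency-ranked per-origin matrices.

Masking is carried by ``numpy.ma`` arrays throughout; masked bins never
re-enter downstream arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import numpy.ma as ma

from .genome import GenomeModel, Origin
from .simulate import StrandedRead, WATSON

__all__ = [
    "StrandedBinTrack",
    "BiasTrack",
    "OriginBiasProfile",
    "count_stranded_reads",
    "compute_bias",
    "normalize_bias",
    "smooth_bias",
    "aggregate_origins",
    "leading_bias_score",
]

DEFAULT_BIN_WIDTH = 5_000  # bp
DEFAULT_MIN_READS = 4
DEFAULT_FLANK_BINS = 5  # per side -> 11-bin centered window


@dataclass
class StrandedBinTrack:
    """Per-bin Watson/Crick read tallies, tiled from coordinate 0."""

    bin_width: int
    watson: dict[str, np.ndarray]
    crick: dict[str, np.ndarray]
    n_rejected: int = 0

    @property
    def chroms(self) -> list[str]:
        return list(self.watson)

    def total(self, chrom: str) -> np.ndarray:
        return self.watson[chrom] + self.crick[chrom]

    @property
    def n_assigned(self) -> int:
        return int(sum(self.watson[c].sum() + self.crick[c].sum() for c in self.watson))


@dataclass
class BiasTrack:
    """Per-bin bias values in [-1, 1] with a coverage mask.

    ``values`` maps chromosome name to a masked array; a bin is masked
    wherever the raw track had fewer than ``min_reads`` reads (and wherever
    masking propagated through normalization/smoothing). ``provenance``
    records the processing stages applied, in order.
    """

    bin_width: int
    values: dict[str, ma.MaskedArray]
    min_reads: int
    provenance: tuple[str, ...] = ("raw",)

    @property
    def chroms(self) -> list[str]:
        return list(self.values)

    def n_masked(self) -> int:
        return int(sum(ma.getmaskarray(v).sum() for v in self.values.values()))

    def n_bins(self) -> int:
        return int(sum(v.size for v in self.values.values()))


def count_stranded_reads(
    reads: Iterable[StrandedRead],
    genome: GenomeModel,
    bin_width: int = DEFAULT_BIN_WIDTH,
) -> StrandedBinTrack:
    """Tally Watson and Crick reads into fixed-width bins by read midpoint.

    Each read lands in exactly one bin (``midpoint // bin_width``). Reads on
    chromosomes absent from the genome raise an error listing the offending
    records; reads whose midpoint falls beyond the chromosome end are
    rejected and counted in ``n_rejected``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lengths = genome.chrom_lengths
    watson = {c: np.zeros(-(-l // bin_width), dtype=np.int64) for c, l in genome.chromosomes}
    crick = {c: np.zeros_like(watson[c]) for c in watson}

    unknown: list[StrandedRead] = []
    n_rejected = 0
    by_chrom: dict[str, tuple[list[int], list[bool]]] = {c: ([], []) for c in watson}
    for read in reads:
        if read.chrom not in lengths:
            unknown.append(read)
            if len(unknown) >= 5:
                break
            continue
        mids, is_w = by_chrom[read.chrom]
        mids.append(read.midpoint)
        is_w.append(read.strand == WATSON)
    if unknown:
        listing = "; ".join(f"{r.chrom}:{r.start}-{r.end}" for r in unknown)
        raise ValueError(f"reads on unknown chromosomes: {listing}")

    for chrom, (mids, is_w) in by_chrom.items():
        if not mids:
            continue
        mid_arr = np.asarray(mids)
        w_arr = np.asarray(is_w)
        ok = (mid_arr >= 0) & (mid_arr < lengths[chrom])
        n_rejected += int((~ok).sum())
        bins = mid_arr[ok] // bin_width
        n_bins = watson[chrom].size
        watson[chrom] += np.bincount(bins[w_arr[ok]], minlength=n_bins)
        crick[chrom] += np.bincount(bins[~w_arr[ok]], minlength=n_bins)
    return StrandedBinTrack(bin_width, watson, crick, n_rejected)


def compute_bias(track: StrandedBinTrack, min_reads: int = DEFAULT_MIN_READS) -> BiasTrack:
    """Per-bin (W - C) / (W + C); bins with W + C < min_reads are masked."""
    values: dict[str, ma.MaskedArray] = {}
    for chrom in track.chroms:
        w = track.watson[chrom].astype(float)
        c = track.crick[chrom].astype(float)
        tot = w + c
        mask = tot < min_reads
        with np.errstate(divide="ignore", invalid="ignore"):
            v = np.where(tot > 0, (w - c) / np.where(tot > 0, tot, 1.0), 0.0)
        values[chrom] = ma.MaskedArray(v, mask=mask)
    return BiasTrack(track.bin_width, values, min_reads, provenance=("raw",))


def _check_compatible(a: BiasTrack, b: BiasTrack) -> None:
    if a.bin_width != b.bin_width:
        raise ValueError(f"bin_width mismatch: {a.bin_width} vs {b.bin_width}")
    if a.chroms != b.chroms or any(a.values[c].shape != b.values[c].shape for c in a.chroms):
        raise ValueError("track shape mismatch: different chromosomes or bin counts")


def normalize_bias(espan: BiasTrack, control: BiasTrack) -> BiasTrack:
    """Subtract the nascent-DNA control bias per bin, propagating masks.

    Subtraction removes additive strand-sampling asymmetry shared with the
    control; the result is clipped back to [-1, 1] (the control bias is
    ~0 wherever both tracks are covered, so clipping is rarely active).
    """
    _check_compatible(espan, control)
    values = {
        c: ma.clip(espan.values[c] - control.values[c], -1.0, 1.0)
        for c in espan.chroms
    }
    return BiasTrack(espan.bin_width, values, espan.min_reads,
                     provenance=espan.provenance + ("normalized",))


def smooth_bias(track: BiasTrack, flank_bins: int = DEFAULT_FLANK_BINS) -> BiasTrack:
    """Masked-aware moving mean over a centered (2*flank_bins + 1)-bin window.

    Each bin becomes the mean of the unmasked values in its window; windows
    truncate at chromosome boundaries; a bin whose window holds no unmasked
    value stays masked. The coverage filter is never re-applied here.
    """
    if flank_bins < 0:
        raise ValueError("flank_bins must be >= 0")
    if flank_bins == 0:
        values = {c: track.values[c].copy() for c in track.chroms}
        return BiasTrack(track.bin_width, values, track.min_reads,
                         provenance=track.provenance + ("smoothed",))
    kernel = np.ones(2 * flank_bins + 1)
    values: dict[str, ma.MaskedArray] = {}
    for chrom in track.chroms:
        v = track.values[chrom]
        mask = ma.getmaskarray(v)
        filled = np.where(mask, 0.0, v.data)
        valid = (~mask).astype(float)
        num = np.convolve(filled, kernel, mode="same")
        den = np.convolve(valid, kernel, mode="same")
        with np.errstate(invalid="ignore"):
            out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        values[chrom] = ma.MaskedArray(out, mask=den == 0)
    return BiasTrack(track.bin_width, values, track.min_reads,
                     provenance=track.provenance + ("smoothed",))


@dataclass
class OriginBiasProfile:
    """Origin-centered bias aggregation.

    ``matrix`` has one row per origin that contributes at least one
    unmasked bin within the flank, ordered by descending efficiency (the
    heatmap order); ``offsets`` are bin-center distances from the origin in
    bp; ``mean_bias`` is the per-offset mean over the unmasked matrix cells
    and ``n_contributing`` the count behind each mean.
    """

    offsets: np.ndarray
    mean_bias: ma.MaskedArray
    n_contributing: np.ndarray
    matrix: ma.MaskedArray
    efficiencies: np.ndarray
    bin_width: int
    n_dropped: int = 0

    @property
    def n_origins(self) -> int:
        return self.matrix.shape[0]


def aggregate_origins(
    bias: BiasTrack,
    origins: Sequence[Origin],
    flank_bp: int,
) -> OriginBiasProfile:
    """Collect bias values at bin offsets around each origin.

    ``flank_bp`` must be a multiple of the bin width. Origins with every
    bin in range masked are dropped (counted in ``n_dropped``); offsets
    falling outside the chromosome are masked. No side-dependent sign
    flipping is done here.
    """
    if not origins:
        raise ValueError("no origins to aggregate over")
    bw = bias.bin_width
    if flank_bp % bw != 0 or flank_bp <= 0:
        raise ValueError(f"flank_bp must be a positive multiple of bin_width={bw}")
    k = flank_bp // bw
    rel = np.arange(-k, k + 1)
    offsets = rel * bw

    ranked = sorted(origins, key=lambda o: (-o.efficiency, o.chrom, o.position))
    rows: list[ma.MaskedArray] = []
    effs: list[float] = []
    n_dropped = 0
    for origin in ranked:
        v = bias.values[origin.chrom]
        idx = origin.position // bw + rel
        row = ma.masked_all(rel.size)
        in_range = (idx >= 0) & (idx < v.size)
        row[in_range] = v[idx[in_range]]
        if ma.getmaskarray(row).all():
            n_dropped += 1
            continue
        rows.append(row)
        effs.append(origin.efficiency)
    if not rows:
        raise ValueError("all origins fully masked within the requested flank")

    matrix = ma.vstack([r[np.newaxis, :] for r in rows])
    mean_bias = matrix.mean(axis=0)
    n_contributing = (~ma.getmaskarray(matrix)).sum(axis=0)
    return OriginBiasProfile(offsets, mean_bias, n_contributing, matrix,
                             np.asarray(effs), bw, n_dropped)


def leading_bias_score(
    profile: OriginBiasProfile,
    inner_bp: int | None = None,
    outer_bp: int | None = None,
) -> float:
    """Scalar leading-strand enrichment summary of an origin profile.

    Half the difference between the mean bias over right offsets in
    [inner_bp, outer_bp] and left offsets in [-outer_bp, -inner_bp],
    averaged over all unmasked per-origin matrix cells. Positive values mean
    leading-strand enrichment under the module's strand convention.
    """
    inner = profile.bin_width if inner_bp is None else inner_bp
    outer = int(profile.offsets.max()) if outer_bp is None else outer_bp
    if not (0 <= inner < outer):
        raise ValueError("need 0 <= inner_bp < outer_bp")
    if outer > profile.offsets.max():
        raise ValueError("outer_bp exceeds the profile flank")
    right = (profile.offsets >= inner) & (profile.offsets <= outer)
    left = (profile.offsets <= -inner) & (profile.offsets >= -outer)
    right_mean = profile.matrix[:, right].mean()
    left_mean = profile.matrix[:, left].mean()
    if right_mean is ma.masked or left_mean is ma.masked:
        raise ValueError("all cells masked in one flank; cannot score")
    return 0.5 * (float(right_mean) - float(left_mean))
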