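"""Synthetic read-outs for replication-coupled histone recycling.

Three generators share one genome and one root seed:

* :func:`simulate_espan` — strand-resolved reads from parental histones
  deposited behind bidirectional forks during a BrdU pulse, plus the matched
  unbiased nascent-DNA (BrdU-IP) control.
* :func:`simulate_cutrun_timecourse` — bulk labeled-histone coverage over a
  chase time-course, with a human spike-in admixture, where the labeled
  parental pool is constant while chromatin content grows with the
  replicated fraction.
* :func:`simulate_live_cell` — per-cell integrated-signal traces through one
  division (mother and two daughters), with optional photobleaching,
  incomplete recycling, and a geminin cell-cycle channel.

Strand convention (single constant, used everywhere): for a rightward-moving
fork the nascent leading strand is the Watson (plus) strand. Hence a sample
enriched on leading strands yields Watson-excess right of an origin and
Crick-excess left of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genome import GenomeModel

__all__ = [
    "StrandedRead",
    "TransferParams",
    "SimulationConfig",
    "CutRunSample",
    "GENOTYPE_PRESETS",
    "simulate_espan",
    "simulate_cutrun_timecourse",
    "simulate_live_cell",
]

#: Watson == plus/forward reference strand; a rightward fork's nascent
#: leading strand maps to Watson.
WATSON = "W"
CRICK = "C"

_STRANDED_ASSAYS = ("espan", "brdu_input")
_ASSAYS = _STRANDED_ASSAYS + ("cuttag", "cutrun_mouse", "cutrun_human")


@dataclass(slots=True)
class StrandedRead:
    """A single read record with a Watson/Crick strand label."""

    chrom: str
    start: int
    end: int
    strand: str
    assay_label: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"read requires start < end, got [{self.start}, {self.end})")
        if self.assay_label not in _ASSAYS:
            raise ValueError(f"unknown assay label {self.assay_label!r}")
        if self.strand not in (WATSON, CRICK):
            raise ValueError(f"strand must be 'W' or 'C', got {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class TransferParams:
    """Parental-histone transfer knobs for one genotype.

    ``p_leading`` — probability that a recycled parental histone lands on
    the leading strand; ``retain_prob`` — probability a parental histone is
    recycled at all during one S phase; ``bleach_rate`` — per-hour
    fractional fluorescent-signal loss in live-cell imaging.

    The preset values in :data:`GENOTYPE_PRESETS` are simulator knobs chosen
    to reproduce the qualitative genotype ordering of leading-strand bias;
    they are not measurements.
    """

    genotype: str
    p_leading: float
    retain_prob: float = 1.0
    bleach_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_leading <= 1.0):
            raise ValueError(f"p_leading must be in [0, 1], got {self.p_leading}")
        if not (0.0 <= self.retain_prob <= 1.0):
            raise ValueError(f"retain_prob must be in [0, 1], got {self.retain_prob}")
        if self.bleach_rate < 0:
            raise ValueError("bleach_rate must be >= 0")

    def with_(self, **kwargs) -> "TransferParams":
        return replace(self, **kwargs)


GENOTYPE_PRESETS: dict[str, TransferParams] = {
    # WT: slight leading-strand tilt; both transfer pathways intact.
    "WT": TransferParams("WT", p_leading=0.55, retain_prob=1.0),
    # Lagging-strand pathway (Mcm2-Pola1) broken -> leading bias increases.
    "Mcm2-2A": TransferParams("Mcm2-2A", p_leading=0.75, retain_prob=0.90),
    "Pola1-2A": TransferParams("Pola1-2A", p_leading=0.75, retain_prob=0.90),
    # Leading-strand pathway (Pole3-Pole4) broken -> bias tips toward lagging.
    "Pole3KO": TransferParams("Pole3KO", p_leading=0.40, retain_prob=0.90),
    "Pole4KO": TransferParams("Pole4KO", p_leading=0.40, retain_prob=0.90),
    # Both pathways broken: bias back near WT, overall retention lowest.
    "Mcm2-2A+Pole4KO": TransferParams("Mcm2-2A+Pole4KO", p_leading=0.55, retain_prob=0.85),
}


@dataclass
class SimulationConfig:
    """Shared simulation settings.

    Defaults mirror the experimental conditions the analyses assume: a
    40-minute BrdU pulse, 20% human spike-in cells, 200 bp nucleosome
    spacing, 100 bp reads centered on the histone position, and a fork speed
    of 1000 bp/min (so a pulse replicates ~40 kb on each side of a fired
    origin).
    """

    seed: int = 0
    n_cells: int = 20
    n_reads: int | None = None
    fork_speed: float = 1000.0  # bp per minute
    pulse_minutes: float = 40.0
    nucleosome_spacing: int = 200
    read_length: int = 100
    spikein_fraction: float = 0.20
    density_bin: int = 500  # sampling granularity for bulk coverage weights
    geminin_noise_sd: float = 0.02
    signal_cv: float = 0.2
    partition_concentration: float = 50.0
    n_histone_units: int = 10_000

    def __post_init__(self) -> None:
        if not (0.0 <= self.spikein_fraction < 1.0):
            raise ValueError("spikein_fraction must be in [0, 1)")
        if self.fork_speed <= 0 or self.pulse_minutes <= 0:
            raise ValueError("fork_speed and pulse_minutes must be positive")
        if self.nucleosome_spacing <= 0 or self.read_length <= 0:
            raise ValueError("nucleosome_spacing and read_length must be positive")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")

    @property
    def pulse_window_bp(self) -> int:
        """Replicated window on each side of a fired origin."""
        return int(self.fork_speed * self.pulse_minutes)


def _child_rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    """Deterministic per-assay child stream from the one root seed."""
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), int(stream)]))


def _make_reads(chrom: str, midpoints: np.ndarray, strands: np.ndarray,
                read_length: int, chrom_len: int, assay: str) -> list[StrandedRead]:
    half = read_length // 2
    starts = midpoints - half
    ends = starts + read_length
    ok = (starts >= 0) & (ends <= chrom_len)
    return [
        StrandedRead(chrom, int(s), int(e), WATSON if w else CRICK, assay)
        for s, e, w in zip(starts[ok], ends[ok], strands[ok])
    ]


def simulate_espan(
    genome: GenomeModel,
    params: TransferParams,
    config: SimulationConfig,
) -> tuple[list[StrandedRead], list[StrandedRead]]:
    """Simulate strand-resolved parental-histone reads plus the BrdU control.

    Per cell-equivalent, each origin fires independently with probability
    equal to its efficiency and replicates ``fork_speed * pulse_minutes`` bp
    on each side. Parental histones sit at ``nucleosome_spacing`` intervals
    inside the replicated window, are recycled with ``retain_prob``, and
    land on the leading strand with ``p_leading`` (else lagging). The strand
    letter follows the module convention: leading right of the origin is
    Watson, leading left is Crick. Control reads are drawn uniformly from
    both nascent strands of the same windows.

    When ``config.n_reads`` is set, both read sets are shuffled and
    truncated to that size (deterministically).
    """
    rng = _child_rng(config, 1)
    lengths = genome.chrom_lengths
    window = config.pulse_window_bp
    spacing = config.nucleosome_spacing

    espan: list[StrandedRead] = []
    brdu: list[StrandedRead] = []
    # Nucleosome slot offsets relative to the origin, symmetric, never 0.
    offsets = np.arange(-window, window, spacing) + spacing // 2

    for _ in range(config.n_cells):
        for origin in genome.origins:
            if rng.random() >= origin.efficiency:
                continue
            chrom_len = lengths[origin.chrom]
            mids = origin.position + offsets
            in_chrom = (mids >= 0) & (mids < chrom_len)
            mids = mids[in_chrom]
            is_right = offsets[in_chrom] >= 0
            n = mids.size
            if n == 0:
                continue

            retained = rng.random(n) < params.retain_prob
            leading = rng.random(n) < params.p_leading
            # leading + right -> W; leading + left -> C; lagging flips.
            is_watson = leading == is_right
            espan.extend(
                _make_reads(origin.chrom, mids[retained], is_watson[retained],
                            config.read_length, chrom_len, "espan")
            )

            # Nascent-DNA control: uniform positions, both strands equally.
            ctrl_mids = origin.position + rng.integers(-window, window, n)
            ctrl_mids = ctrl_mids[(ctrl_mids >= 0) & (ctrl_mids < chrom_len)]
            ctrl_watson = rng.random(ctrl_mids.size) < 0.5
            brdu.extend(
                _make_reads(origin.chrom, ctrl_mids, ctrl_watson,
                            config.read_length, chrom_len, "brdu_input")
            )

    if config.n_reads is not None:
        for reads in (espan, brdu):
            if len(reads) > config.n_reads:
                keep = rng.permutation(len(reads))[: config.n_reads]
                reads[:] = [reads[i] for i in sorted(keep)]
    return espan, brdu


@dataclass
class CutRunSample:
    """One time point of the spike-in CUT&RUN simulation."""

    time_h: float
    replicated_fraction: float
    mouse_reads: list[StrandedRead]
    human_read_count: int

    @property
    def mouse_library_size(self) -> int:
        return len(self.mouse_reads)

    @property
    def human_library_size(self) -> int:
        return self.human_read_count

    @property
    def total_reads(self) -> int:
        return self.mouse_library_size + self.human_read_count


def _h33_weight_profile(genome: GenomeModel, bin_width: int) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Per-bin chromatin sampling weights: baseline 1 plus h33_weight in gene bodies."""
    chroms: list[str] = []
    weights: list[np.ndarray] = []
    starts: list[np.ndarray] = []
    for cname, clen in genome.chromosomes:
        n_bins = -(-clen // bin_width)
        w = np.ones(n_bins)
        for g in genome.genes:
            if g.chrom != cname:
                continue
            b0, b1 = g.tss // bin_width, -(-g.tts // bin_width)
            w[b0:b1] += g.h33_weight
        chroms.extend([cname] * n_bins)
        weights.append(w)
        starts.append(np.arange(n_bins) * bin_width)
    return chroms, np.concatenate(starts), np.concatenate(weights)


def simulate_cutrun_timecourse(
    genome: GenomeModel,
    times: list[float],
    replicated_fraction_at_time: dict[float, float],
    config: SimulationConfig,
) -> dict[float, CutRunSample]:
    """Simulate labeled-histone coverage over a chase with human spike-in.

    The labeled parental pool per cell is constant while chromatin content
    grows by a factor ``1 + f`` with the replicated fraction ``f``, so the
    labeled fraction of mouse chromatin — and with it the mouse read yield
    per cell — dilutes as ``1 / (1 + f)``. Spike-in (human) cells make up
    ``spikein_fraction`` of labeled cells with a fixed per-cell yield, so
    the expected human share of a library of ``n_reads`` total reads at
    replicated fraction ``f`` is ``s / (s + (1 - s) / (1 + f))``.

    Mouse read positions are drawn from the H3.3-enrichment weight profile
    around genes. Returns one :class:`CutRunSample` per requested time.
    """
    n_total = config.n_reads if config.n_reads is not None else 100_000
    s = config.spikein_fraction
    chrom_of_bin, bin_start, weights = _h33_weight_profile(genome, config.density_bin)
    p_bins = weights / weights.sum()
    lengths = genome.chrom_lengths

    out: dict[float, CutRunSample] = {}
    for i, t in enumerate(times):
        f = float(replicated_fraction_at_time[t])
        if not (0.0 <= f <= 1.0):
            raise ValueError(f"replicated fraction at t={t} must be in [0, 1], got {f}")
        rng = _child_rng(config, 100 + i)
        mouse_yield = (1.0 - s) / (1.0 + f)
        p_human = s / (s + mouse_yield)
        n_human = int(rng.binomial(n_total, p_human))
        n_mouse = n_total - n_human

        idx = rng.choice(p_bins.size, size=n_mouse, p=p_bins)
        within = rng.integers(0, config.density_bin, n_mouse)
        watson = rng.random(n_mouse) < 0.5

        mouse_reads: list[StrandedRead] = []
        half = config.read_length // 2
        for j in range(n_mouse):
            chrom = chrom_of_bin[idx[j]]
            clen = lengths[chrom]
            mid = int(bin_start[idx[j]] + within[j])
            start = min(max(mid - half, 0), clen - config.read_length)
            mouse_reads.append(StrandedRead(chrom, start, start + config.read_length,
                                            WATSON if watson[j] else CRICK, "cutrun_mouse"))
        out[t] = CutRunSample(t, f, mouse_reads, n_human)
    return out


def simulate_live_cell(
    params: TransferParams,
    n_cells: int,
    frame_minutes: float = 20.0,
    horizon_hours: float = 16.0,
    seed: int = 0,
    *,
    config: SimulationConfig | None = None,
) -> list["CellTrace"]:
    """Simulate mother/daughter integrated-signal traces through one division.

    Each mother divides at a frame-aligned mitosis time between 11.5 h and
    14.5 h, so the G1/S point 11 h before mitosis falls inside the trace.
    The mother's signal decays continuously at ``bleach_rate`` per hour and
    loses ``1 - retain_prob`` of its histone units across S phase (G1/S to
    1 h before mitosis), with the retained fraction drawn binomially over
    ``n_histone_units`` per cell. At mitosis the remaining signal is split
    between two daughters by a symmetric Beta-distributed fraction (mean
    0.5); daughter signals continue to bleach. The geminin channel is high
    from G1/S until mitosis, low elsewhere, plus Gaussian noise.
    """
    from .livecell import CellTrace  # avoid import cycle at module load

    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    cfg = config if config is not None else SimulationConfig(seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 200]))

    frame_h = frame_minutes / 60.0
    n_frames = int(round(horizon_hours / frame_h)) + 1
    t = np.arange(n_frames) * frame_h
    lo = int(np.ceil(11.5 / frame_h))
    hi = int(np.floor(14.5 / frame_h))
    beta = params.bleach_rate
    conc = cfg.partition_concentration

    traces: list[CellTrace] = []
    for i in range(n_cells):
        s0 = float(rng.lognormal(np.log(1000.0), cfg.signal_cv))
        mit_idx = int(rng.integers(lo, hi + 1))
        t_mit = t[mit_idx]
        t_g1s, t_g2 = t_mit - 11.0, t_mit - 1.0

        if params.retain_prob in (0.0, 1.0):
            retained = params.retain_prob
        else:
            retained = rng.binomial(cfg.n_histone_units, params.retain_prob) / cfg.n_histone_units

        # Retention loss accrues across S phase; exact endpoints 1 -> retained.
        progress = np.clip((t - t_g1s) / (t_g2 - t_g1s), 0.0, 1.0)
        retention = np.where(progress == 0.0, 1.0,
                             np.where(progress == 1.0, retained,
                                      np.power(retained, progress, where=retained > 0,
                                               out=np.zeros_like(progress))))
        decay = np.exp(-beta * t) if beta > 0 else np.ones_like(t)
        signal = s0 * decay * retention

        mother_id = f"cell{i:04d}"
        mother_t = t[: mit_idx + 1]
        gem = np.full(mit_idx + 1, 0.05)
        gem[(mother_t >= t_g1s) & (mother_t < t_mit)] = 1.0
        gem = gem + rng.normal(0.0, cfg.geminin_noise_sd, gem.size)
        traces.append(CellTrace(mother_id, None, mother_t.copy(),
                                signal[: mit_idx + 1].copy(), gem, float(t_mit)))

        m = float(signal[mit_idx])  # signal handed to the daughters
        q = float(rng.beta(conc, conc))
        share1 = q * m
        share2 = m - share1
        # enforce bit-exact conservation of the split: rounding can leave
        # share1 + share2 one ulp off m, so alternately re-derive each share
        # from the other; m/2 + m/2 == m always holds as a last resort
        for _ in range(4):
            if share1 + share2 == m:
                break
            share1 = m - share2
            if share1 + share2 == m:
                break
            share2 = m - share1
        if share1 + share2 != m:
            share1 = share2 = m / 2.0
        d_t = t[mit_idx + 1:]
        d_decay = np.exp(-beta * (d_t - t_mit)) if beta > 0 else np.ones_like(d_t)
        for k, share in ((1, share1), (2, share2)):
            d_gem = np.full(d_t.size, 0.05) + rng.normal(0.0, cfg.geminin_noise_sd, d_t.size)
            traces.append(CellTrace(f"{mother_id}_d{k}", mother_id, d_t.copy(),
                                    share * d_decay, d_gem, None))
    return traces
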