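"""End-to-end orchestration: simulate -> bias -> coverage -> live-cell.

A :class:`RunConfig` fully determines a run; identical config + seed gives
identical output checksums. Every stage writes its numeric outputs as
plain-text TSV/BED/bedGraph (the contract); profile plots are courtesy
outputs. A manifest records the config hash, seed, and per-file SHA-256
checksums of the numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import bias as bias_mod
from . import coverage as cov_mod
from . import io as fio
from . import livecell as lc
from .genome import make_genome
from .simulate import (GENOTYPE_PRESETS, SimulationConfig, simulate_cutrun_timecourse,
                       simulate_espan, simulate_live_cell)

__all__ = ["RunConfig", "SimSection", "BiasSection", "CoverageSection",
           "LiveCellSection", "run_pipeline", "load_config"]

logger = logging.getLogger("forkhist")


def _from_dict(cls, data: dict[str, Any]):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if dataclasses.is_dataclass(f.type) if isinstance(f.type, type) else False:
            value = _from_dict(f.type, value)
        kwargs[f.name] = value
    return cls(**kwargs)


@dataclass
class SimSection:
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_origins: int = 8
    n_genes: int = 40
    n_cells: int = 20
    n_reads: int | None = None
    fork_speed: float = 1000.0
    pulse_minutes: float = 40.0  # BrdU pulse length
    nucleosome_spacing: int = 200
    read_length: int = 100
    spikein_fraction: float = 0.20  # human spike-in share of labeled cells
    timecourse_hours: tuple[float, ...] = (0.0, 5.0, 11.0)
    replicated_fractions: tuple[float, ...] = (0.0, 0.5, 1.0)
    cutrun_reads: int = 100_000

    def __post_init__(self) -> None:
        self.timecourse_hours = tuple(float(t) for t in self.timecourse_hours)
        self.replicated_fractions = tuple(float(f) for f in self.replicated_fractions)
        if len(self.timecourse_hours) != len(self.replicated_fractions):
            raise ValueError("timecourse_hours and replicated_fractions must align")


@dataclass
class BiasSection:
    bin_width: int = 5_000
    min_reads: int = 4
    flank_bins: int = 5
    aggregate_flank_bp: int = 40_000
    score_inner_bp: int = 5_000
    score_outer_bp: int = 40_000


@dataclass
class CoverageSection:
    window_bp: int = 50_000
    density_bin: int = 1_000
    normalization: str = "spikein"
    scaled_bins: int = 60
    flank_bp: int = 2_000
    flank_bins: int = 20


@dataclass
class LiveCellSection:
    mode: str = "offset"
    g1s_offset_hours: float = 11.0
    g2_offset_hours: float = 1.0
    next_g1_offset_hours: float = 1.0
    n_cells: int = 100
    frame_minutes: float = 20.0
    horizon_hours: float = 16.0


@dataclass
class RunConfig:
    seed: int = 0
    genotype: str = "WT"
    out_dir: str = "forkhist_run"
    sim: SimSection = field(default_factory=SimSection)
    bias: BiasSection = field(default_factory=BiasSection)
    coverage: CoverageSection = field(default_factory=CoverageSection)
    livecell: LiveCellSection = field(default_factory=LiveCellSection)

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPE_PRESETS:
            raise ValueError(f"unknown genotype {self.genotype!r}; "
                             f"choose from {sorted(GENOTYPE_PRESETS)}")

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        data = dict(data)
        for key, sub in (("sim", SimSection), ("bias", BiasSection),
                         ("coverage", CoverageSection), ("livecell", LiveCellSection)):
            if key in data and isinstance(data[key], dict):
                data[key] = _from_dict(sub, data[key])
        return _from_dict(cls, data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(canonical.encode()).hexdigest()


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _sim_config(cfg: RunConfig, n_reads: int | None = None) -> SimulationConfig:
    s = cfg.sim
    return SimulationConfig(
        seed=cfg.seed, n_cells=s.n_cells, n_reads=n_reads if n_reads is not None else s.n_reads,
        fork_speed=s.fork_speed, pulse_minutes=s.pulse_minutes,
        nucleosome_spacing=s.nucleosome_spacing, read_length=s.read_length,
        spikein_fraction=s.spikein_fraction,
    )


def _plot_profiles(profile, metagene, out_dir: Path) -> list[str]:
    """Courtesy plots; numeric TSVs remain the contract."""
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception:  # pragma: no cover - plotting is optional
        logger.warning("matplotlib unavailable; skipping plots")
        return []
    written = []
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(profile.offsets / 1000.0, profile.mean_bias.filled(np.nan))
    ax.axhline(0, color="grey", lw=0.6)
    ax.set_xlabel("distance from origin (kb)")
    ax.set_ylabel("mean strand bias (W-C)/(W+C)")
    fig.tight_layout()
    p = out_dir / "origin_bias_profile.png"
    fig.savefig(p, metadata={"Date": None, "Software": None})
    plt.close(fig)
    written.append(p.name)

    fig, ax = plt.subplots(figsize=(5, 3.2))
    for q in (1, 2, 3, 4):
        ax.plot(metagene.by_quartile[q], label=f"Q{q}")
    ax.set_xlabel("scaled position (upstream - body - downstream)")
    ax.set_ylabel("mean density")
    ax.legend(fontsize=7)
    fig.tight_layout()
    p = out_dir / "metagene_profile.png"
    fig.savefig(p, metadata={"Date": None, "Software": None})
    plt.close(fig)
    written.append(p.name)
    return written


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict[str, Any]:
    """Execute the full chain and return the manifest.

    Stages: genome -> strand-resolved simulation -> count -> bias ->
    BrdU-control normalization -> smoothing -> origin aggregation (+
    coverage time-course, + live-cell quantification). Any stage error
    aborts with the stage named in the log.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    checksummed: list[Path] = []
    extra_outputs: list[str] = []
    stage = "setup"
    try:
        logger.info("run seed=%d genotype=%s hash=%s", config.seed, config.genotype,
                    config.config_hash())
        params = GENOTYPE_PRESETS[config.genotype]

        stage = "genome"
        genome = make_genome(config.sim.n_chroms, config.sim.chrom_length,
                             config.sim.n_origins, config.sim.n_genes, config.seed)
        fio.write_genome(genome, out / "genome")
        checksummed += sorted((out / "genome").iterdir())

        stage = "simulate-espan"
        sim_cfg = _sim_config(config)
        espan, brdu = simulate_espan(genome, params, sim_cfg)
        fio.write_bed(fio.reads_to_bed(espan), out / "espan_reads.bed")
        fio.write_bed(fio.reads_to_bed(brdu), out / "brdu_reads.bed")
        checksummed += [out / "espan_reads.bed", out / "brdu_reads.bed"]
        logger.info("espan reads=%d brdu reads=%d", len(espan), len(brdu))

        stage = "strand-bias"
        bw = config.bias.bin_width
        espan_track = bias_mod.count_stranded_reads(espan, genome, bw)
        brdu_track = bias_mod.count_stranded_reads(brdu, genome, bw)
        if espan_track.n_rejected or brdu_track.n_rejected:
            logger.warning("rejected reads beyond chromosome ends: espan=%d brdu=%d",
                           espan_track.n_rejected, brdu_track.n_rejected)
        espan_bias = bias_mod.compute_bias(espan_track, config.bias.min_reads)
        brdu_bias = bias_mod.compute_bias(brdu_track, config.bias.min_reads)
        norm = bias_mod.normalize_bias(espan_bias, brdu_bias)
        smooth = bias_mod.smooth_bias(norm, config.bias.flank_bins)
        for name, tr in (("espan_bias_raw", espan_bias), ("bias_normalized", norm),
                         ("bias_smoothed", smooth)):
            fio.write_bedgraph(tr.values, bw, out / f"{name}.bedgraph")
            checksummed.append(out / f"{name}.bedgraph")
        logger.info("masked bins raw=%d normalized=%d", espan_bias.n_masked(), norm.n_masked())

        stage = "origin-aggregation"
        profile = bias_mod.aggregate_origins(smooth, genome.origins,
                                             config.bias.aggregate_flank_bp)
        score = bias_mod.leading_bias_score(profile, config.bias.score_inner_bp,
                                            config.bias.score_outer_bp)
        prof_df = pd.DataFrame({
            "offset_bp": profile.offsets,
            "mean_bias": profile.mean_bias.filled(np.nan),
            "n_contributing": profile.n_contributing,
        })
        prof_df.to_csv(out / "origin_bias_profile.tsv", sep="\t", index=False)
        mat_df = pd.DataFrame(profile.matrix.filled(np.nan),
                              columns=[str(o) for o in profile.offsets])
        mat_df.insert(0, "efficiency", profile.efficiencies)
        mat_df.to_csv(out / "origin_bias_matrix.tsv", sep="\t", index=False)
        checksummed += [out / "origin_bias_profile.tsv", out / "origin_bias_matrix.tsv"]
        logger.info("leading_bias_score=%.4f over %d origins", score, profile.n_origins)

        stage = "coverage"
        cov_cfg = _sim_config(config, n_reads=config.sim.cutrun_reads)
        frac = dict(zip(config.sim.timecourse_hours, config.sim.replicated_fractions))
        samples = simulate_cutrun_timecourse(genome, list(config.sim.timecourse_hours),
                                             frac, cov_cfg)
        lib_rows, region_frames, tracks_rpm, tracks_spike, labels = [], [], [], [], []
        for t, sample in samples.items():
            counts = cov_mod.bin_reads(sample.mouse_reads, genome,
                                       config.coverage.density_bin)
            rpm = cov_mod.rpm_normalize(counts, sample.mouse_library_size)
            spike = cov_mod.spikein_normalize(counts, sample.human_library_size)
            tracks_rpm.append(rpm)
            tracks_spike.append(spike)
            labels.append(f"T{t:g}")
            lib_rows.append((f"T{t:g}", sample.mouse_library_size,
                             sample.human_library_size))
            for norm_name, track in (("rpm", rpm), ("spikein", spike)):
                df = cov_mod.region_density(track, genome.h33_regions)
                df.insert(0, "time", f"T{t:g}")
                df.insert(1, "normalization", norm_name)
                region_frames.append(df)
        pd.DataFrame(lib_rows, columns=["sample", "mapped_reads", "human_reads"]).to_csv(
            out / "library_sizes.tsv", sep="\t", index=False)
        pd.concat(region_frames, ignore_index=True).to_csv(
            out / "h33_region_density.tsv", sep="\t", index=False)
        corr = cov_mod.correlation_matrix(tracks_rpm, config.coverage.window_bp, labels)
        corr.to_csv(out / "correlation_matrix.tsv", sep="\t")
        metagene = cov_mod.metagene_profile(
            tracks_rpm[0], genome.genes, config.coverage.scaled_bins,
            config.coverage.flank_bp, config.coverage.flank_bins)
        meta_df = pd.DataFrame({f"Q{q}": metagene.by_quartile[q] for q in (1, 2, 3, 4)})
        meta_df.to_csv(out / "metagene_profile.tsv", sep="\t", index=False)
        checksummed += [out / "library_sizes.tsv", out / "h33_region_density.tsv",
                        out / "correlation_matrix.tsv", out / "metagene_profile.tsv"]

        stage = "live-cell"
        traces = simulate_live_cell(params, config.livecell.n_cells,
                                    config.livecell.frame_minutes,
                                    config.livecell.horizon_hours,
                                    seed=config.seed, config=sim_cfg)
        fio.write_traces_tsv(traces, out / "cell_traces.tsv")
        offsets = lc.PhaseOffsets(config.livecell.g1s_offset_hours,
                                  config.livecell.g2_offset_hours,
                                  config.livecell.next_g1_offset_hours)
        calls = {}
        n_call_failed = 0
        for tr in traces:
            if tr.parent_id is not None:
                continue
            try:
                calls[tr.cell_id] = lc.call_phases(tr, config.livecell.mode, offsets)
            except ValueError:
                n_call_failed += 1
        if n_call_failed:
            logger.warning("phase calling failed for %d cells", n_call_failed)
        stats = lc.quantify_inheritance(traces, calls)
        stats.per_cell.to_csv(out / "inheritance_per_cell.tsv", sep="\t", index=False)
        summary_df = pd.DataFrame(
            [(k, m, s, stats.n) for k, (m, s) in stats.summary.items()],
            columns=["quantity", "mean", "sd", "n"])
        summary_df.to_csv(out / "inheritance_summary.tsv", sep="\t", index=False)
        duration = lc.g1s_to_mitosis_duration(traces)
        pd.DataFrame([{
            "genotype": config.genotype, "mean_hours": duration.mean_hours,
            "sd_hours": duration.sd_hours, "n": duration.n,
            "n_failed": duration.n_failed,
        }]).to_csv(out / "g1s_to_mitosis_duration.tsv", sep="\t", index=False)
        checksummed += [out / "cell_traces.tsv", out / "inheritance_per_cell.tsv",
                        out / "inheritance_summary.tsv",
                        out / "g1s_to_mitosis_duration.tsv"]
        if stats.n_excluded:
            logger.warning("cells excluded from inheritance stats: %d", stats.n_excluded)

        stage = "plots"
        extra_outputs = _plot_profiles(profile, metagene, out)

        stage = "manifest"
        manifest = {
            "seed": config.seed,
            "genotype": config.genotype,
            "config_hash": config.config_hash(),
            "leading_bias_score": score,
            "g1s_to_mitosis_mean_hours": duration.mean_hours,
            "files": {p.name if p.parent == out else f"genome/{p.name}": _sha256(p)
                      for p in checksummed},
            "plots": extra_outputs,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        logger.info("run complete: %d checksummed outputs", len(checksummed))
        return manifest
    except Exception as exc:
        logger.exception("pipeline failed at stage %r", stage)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
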