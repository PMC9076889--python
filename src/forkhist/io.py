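"""Plain-text I/O: BED6, bedGraph, and TSV round-trips.

Conventions: BED is tab-separated, 0-based half-open; the BED strand column
maps ``+`` to Watson and ``-`` to Crick; origin BED files carry the firing
efficiency in the score column; bedGraph files omit masked bins, and
re-reading restores the mask on the missing bins. Malformed lines are
reported with their line numbers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import numpy.ma as ma
import pandas as pd

from .genome import GeneModel, GenomeModel, Origin
from .simulate import CRICK, WATSON, StrandedRead

__all__ = [
    "BedParseError",
    "read_bed",
    "write_bed",
    "reads_to_bed",
    "bed_to_reads",
    "origins_to_bed",
    "bed_to_origins",
    "write_bedgraph",
    "read_bedgraph",
    "write_traces_tsv",
    "read_traces_tsv",
    "write_genome",
    "read_genome",
]

_BED_STRANDS = ("+", "-", ".")


class BedParseError(ValueError):
    """A malformed BED/bedGraph line, reported with its line number."""


def read_bed(path: str | Path, chrom_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Read a BED6 file into a DataFrame, validating each line."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 BED fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise BedParseError(f"{path}:{lineno}: requires 0 <= start < end, "
                                    f"got [{start}, {end})")
            if chrom_lengths is not None:
                if chrom not in chrom_lengths:
                    raise BedParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                if end > chrom_lengths[chrom]:
                    raise BedParseError(f"{path}:{lineno}: end {end} beyond "
                                        f"chromosome length {chrom_lengths[chrom]}")
            name = fields[3] if len(fields) > 3 else "."
            try:
                score = float(fields[4]) if len(fields) > 4 else 0.0
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in _BED_STRANDS:
                raise BedParseError(f"{path}:{lineno}: unknown strand {strand!r}")
            rows.append((chrom, start, end, name, score, strand))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def write_bed(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, sep="\t", header=False, index=False,
                   columns=["chrom", "start", "end", "name", "score", "strand"])


def reads_to_bed(reads: Iterable[StrandedRead]) -> pd.DataFrame:
    rows = [(r.chrom, r.start, r.end, r.assay_label, 0,
             "+" if r.strand == WATSON else "-") for r in reads]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def bed_to_reads(bed: pd.DataFrame) -> list[StrandedRead]:
    reads = []
    for row in bed.itertuples(index=False):
        if row.strand not in ("+", "-"):
            raise ValueError(f"read records require a +/- strand, got {row.strand!r}")
        reads.append(StrandedRead(row.chrom, int(row.start), int(row.end),
                                  WATSON if row.strand == "+" else CRICK, row.name))
    return reads


def origins_to_bed(origins: Sequence[Origin]) -> pd.DataFrame:
    rows = [(o.chrom, o.position, o.position + 1, f"origin{i}", o.efficiency, ".")
            for i, o in enumerate(origins)]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def bed_to_origins(bed: pd.DataFrame) -> list[Origin]:
    return sorted(
        (Origin(row.chrom, int(row.start), float(row.score))
         for row in bed.itertuples(index=False)),
        key=lambda o: (o.chrom, o.position),
    )


def write_bedgraph(
    values: dict[str, np.ndarray | ma.MaskedArray],
    bin_width: int,
    path: str | Path,
) -> None:
    """Write per-bin values as bedGraph, omitting masked bins."""
    with open(path, "w") as fh:
        for chrom in values:
            v = values[chrom]
            mask = ma.getmaskarray(v) if isinstance(v, ma.MaskedArray) else np.zeros(len(v), bool)
            data = v.data if isinstance(v, ma.MaskedArray) else np.asarray(v)
            for i in np.nonzero(~mask)[0]:
                fh.write(f"{chrom}\t{i * bin_width}\t{(i + 1) * bin_width}\t{data[i]:.6g}\n")


def read_bedgraph(
    path: str | Path,
    bin_width: int,
    chrom_lengths: dict[str, int],
) -> dict[str, ma.MaskedArray]:
    """Read a bedGraph into per-chromosome masked arrays.

    Bins absent from the file are masked. Intervals must align to the
    ``bin_width`` grid.
    """
    out = {c: ma.masked_all(-(-l // bin_width)) for c, l in chrom_lengths.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise BedParseError(f"{path}:{lineno}: bedGraph needs 4 fields")
            chrom = fields[0]
            if chrom not in out:
                raise BedParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: malformed interval/value") from exc
            if start % bin_width != 0 or (end - start) != bin_width:
                raise BedParseError(
                    f"{path}:{lineno}: interval [{start}, {end}) not aligned "
                    f"to bin width {bin_width}"
                )
            out[chrom][start // bin_width] = value
    return out


def write_traces_tsv(traces, path: str | Path) -> None:
    """Write cell traces as long-format TSV.

    Columns: cell_id, parent_id, time_h, signal, geminin, mitosis_time
    (parent_id/geminin/mitosis_time empty where absent).
    """
    frames = []
    for t in traces:
        df = pd.DataFrame({
            "cell_id": t.cell_id,
            "parent_id": t.parent_id if t.parent_id is not None else "",
            "time_h": t.time_h,
            "signal": t.signal,
            "geminin": t.geminin if t.geminin is not None else np.nan,
            "mitosis_time": t.mitosis_time if t.mitosis_time is not None else np.nan,
        })
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_traces_tsv(path: str | Path):
    """Read traces written by :func:`write_traces_tsv`."""
    from .livecell import CellTrace

    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str})
    traces = []
    for cell_id, group in df.groupby("cell_id", sort=False):
        parent = group["parent_id"].iloc[0]
        parent_id = None if pd.isna(parent) or parent == "" else str(parent)
        geminin = group["geminin"].to_numpy()
        mit = group["mitosis_time"].iloc[0]
        traces.append(CellTrace(
            str(cell_id), parent_id,
            group["time_h"].to_numpy(), group["signal"].to_numpy(),
            None if np.isnan(geminin).all() else geminin,
            None if pd.isna(mit) else float(mit),
        ))
    return traces


def write_genome(genome: GenomeModel, out_dir: str | Path) -> None:
    """Serialize a genome model as TSV/BED files in a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(genome.chromosomes, columns=["chrom", "length"]).to_csv(
        out / "chromosomes.tsv", sep="\t", index=False)
    write_bed(origins_to_bed(genome.origins), out / "origins.bed")
    pd.DataFrame(
        [(g.chrom, g.tss, g.tts, g.strand, g.quartile, g.h33_weight) for g in genome.genes],
        columns=["chrom", "tss", "tts", "strand", "quartile", "h33_weight"],
    ).to_csv(out / "genes.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(c, s, e, f"h33_{i}", 0, ".") for i, (c, s, e) in enumerate(genome.h33_regions)],
        columns=["chrom", "start", "end", "name", "score", "strand"],
    ).pipe(write_bed, out / "h33_regions.bed")


def read_genome(in_dir: str | Path) -> GenomeModel:
    src = Path(in_dir)
    chroms = pd.read_csv(src / "chromosomes.tsv", sep="\t")
    chromosomes = [(str(r.chrom), int(r.length)) for r in chroms.itertuples(index=False)]
    origins = bed_to_origins(read_bed(src / "origins.bed"))
    genes_df = pd.read_csv(src / "genes.tsv", sep="\t")
    genes = [GeneModel(str(r.chrom), int(r.tss), int(r.tts), str(r.strand),
                       int(r.quartile), float(r.h33_weight))
             for r in genes_df.itertuples(index=False)]
    h33 = [(str(r.chrom), int(r.start), int(r.end))
           for r in read_bed(src / "h33_regions.bed").itertuples(index=False)]
    return GenomeModel(chromosomes=chromosomes, origins=origins, genes=genes,
                       h33_regions=h33)
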