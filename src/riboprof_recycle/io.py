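"""Readers and writers for the plain-text formats the pipeline speaks.

Aligned reads travel as BED6 (0-based half-open, name column carries the
read class); density tracks export as bedGraph (one file per strand);
tables as TSV.  Everything is written deterministically (sorted, fixed
float format) so identical runs produce identical bytes.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import Annotation

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
FLOAT_FORMAT = "%.6g"


class DataError(ValueError):
    """Raised for malformed or inconsistent data files."""


def read_bed6(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=BED6_COLUMNS,
        dtype={"chrom": str, "start": np.int64, "end": np.int64,
               "name": str, "score": str, "strand": str},
        comment="#",
    )
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise DataError(f"{path}: {int(bad.sum())} reads with invalid strand")
    if (df["start"] >= df["end"]).any():
        raise DataError(f"{path}: reads with empty or inverted intervals")
    return df


def write_bed6(reads: pd.DataFrame, path: str | Path) -> None:
    reads[BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(track, out_prefix: str | Path) -> list[Path]:
    """Write one bedGraph per strand, run-length collapsing equal counts."""
    paths = []
    for strand, tag in (("+", "plus"), ("-", "minus")):
        path = Path(f"{out_prefix}.{tag}.bedgraph")
        with open(path, "w") as fh:
            for chrom in sorted(track.counts_by_chrom(strand)):
                arr = track.array(chrom, strand)
                # boundaries of constant runs
                edges = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate(([0], edges))
                ends = np.concatenate((edges, [len(arr)]))
                for s, e in zip(starts, ends):
                    v = arr[s]
                    if v:
                        fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")
        paths.append(path)
    return paths


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def write_gff3(ann: Annotation, path: str | Path) -> None:
    """Write CDS features (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(ann.chrom_lengths):
            fh.write(f"##sequence-region {chrom} 1 {ann.chrom_lengths[chrom]}\n")
        for g in sorted(ann.genes, key=lambda g: (g.chrom, g.cds_start)):
            fh.write(
                f"{g.chrom}\triboprof\tCDS\t{g.cds_start + 1}\t{g.cds_end}\t.\t"
                f"{g.strand}\t0\tID={g.gene_id}\n"
            )


def write_tu_table(ann: Annotation, path: str | Path) -> None:
    rows = [
        {
            "tu_id": tu.tu_id,
            "chrom": tu.chrom,
            "strand": tu.strand,
            "tu_start": tu.tu_start,
            "tu_end": tu.tu_end,
            "gene_ids": ",".join(tu.gene_ids),
        }
        for tu in sorted(ann.tus, key=lambda t: (t.chrom, t.tu_start))
    ]
    write_tsv(pd.DataFrame(rows), path)


def write_chrom_lengths(ann: Annotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(ann.chrom_lengths):
            fh.write(f"{chrom}\t{ann.chrom_lengths[chrom]}\n")
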