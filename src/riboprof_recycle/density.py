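"""Footprint 3'-end density tracks, region RPKMs and stop-codon metagenes.

Each ribosome footprint is represented by the genomic position of its
3'-terminal nucleotide: on the plus strand that is ``end - 1`` of the
aligned interval, on the minus strand ``start``.  Densities are counts of
such 3' ends per nt per strand.  Region quantification follows RPKM
(reads per kb of region per million mapped reads), with the last
``exclude_last`` nt of a CDS (strand-aware) removed so that the
termination-peak pileup does not inflate gene-body density.

Metagene profiles average density across genes aligned at a common anchor,
here the final nt of the stop codon (offset 0); negative offsets run into
the CDS, positive offsets into the 3'-UTR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .annotation import Annotation
from .io import DataError


@dataclass
class DensityTrack:
    """Per-(chromosome, strand) arrays of footprint 3'-end counts."""

    counts: dict[tuple[str, str], np.ndarray]
    total_mapped: int
    library_id: str = ""

    def array(self, chrom: str, strand: str) -> np.ndarray:
        try:
            return self.counts[(chrom, strand)]
        except KeyError:
            raise DataError(f"track has no array for ({chrom}, {strand})") from None

    def counts_by_chrom(self, strand: str) -> list[str]:
        return [c for (c, s) in self.counts if s == strand]

    def count_in(self, chrom: str, start: int, end: int, strand: str) -> int:
        arr = self.array(chrom, strand)
        start, end = max(0, start), min(len(arr), end)
        if end <= start:
            return 0
        return int(arr[start:end].sum())

    @property
    def total_assigned(self) -> int:
        return int(sum(arr.sum() for arr in self.counts.values()))

    def scaled(self, factor: int) -> "DensityTrack":
        """Multiply every count (and the library total) by an integer factor."""
        return DensityTrack(
            {k: arr * factor for k, arr in self.counts.items()},
            self.total_mapped * factor,
            self.library_id,
        )


def assign_three_prime_end(
    chrom: str, start: int, end: int, strand: str
) -> tuple[str, str, int]:
    """Map an aligned interval to the genomic position of its 3' end."""
    if end <= start:
        raise DataError(f"empty or inverted read interval [{start}, {end})")
    if strand == "+":
        return chrom, strand, end - 1
    if strand == "-":
        return chrom, strand, start
    raise DataError(f"invalid strand {strand!r}")


def three_prime_positions(reads: pd.DataFrame) -> np.ndarray:
    """Vectorised 3'-end positions for a BED6 frame."""
    if (reads["start"] >= reads["end"]).any():
        raise DataError("reads with empty or inverted intervals")
    return np.where(
        reads["strand"].to_numpy() == "+",
        reads["end"].to_numpy() - 1,
        reads["start"].to_numpy(),
    )


def build_density_track(
    reads: pd.DataFrame, annotation: Annotation, library_id: str = ""
) -> DensityTrack:
    """Count footprint 3' ends per position per strand.

    ``total_mapped`` (the rpm/RPKM denominator) is the number of input
    reads; every read must map to a chromosome known to the annotation.
    """
    lengths = annotation.chrom_lengths
    unknown = sorted(set(reads["chrom"]) - set(lengths))
    if unknown:
        raise DataError(f"reads on unknown chromosome(s): {', '.join(unknown)}")
    counts = {
        (chrom, strand): np.zeros(n, dtype=np.int64)
        for chrom, n in lengths.items()
        for strand in "+-"
    }
    if len(reads):
        pos = three_prime_positions(reads)
        frame = pd.DataFrame(
            {"chrom": reads["chrom"].to_numpy(), "strand": reads["strand"].to_numpy(),
             "pos": pos}
        )
        for (chrom, strand), grp in frame.groupby(["chrom", "strand"], sort=False):
            arr = counts[(chrom, strand)]
            p = grp["pos"].to_numpy()
            if (p < 0).any() or (p >= len(arr)).any():
                raise DataError(f"read 3' ends outside chromosome {chrom}")
            np.add.at(arr, p, 1)
    return DensityTrack(counts, total_mapped=len(reads), library_id=library_id)


def region_rpkm(
    track: DensityTrack,
    chrom: str,
    start: int,
    end: int,
    strand: str,
    exclude_last: int = 0,
) -> float:
    """RPKM of 3'-end counts in a strand-aware interval.

    ``exclude_last`` trims that many nt from the 3' side of the interval
    (high end on '+', low end on '-') before counting; it is applied to
    CDS regions (default 15 in the pipeline) and left at 0 for 3'-UTRs.
    """
    if track.total_mapped <= 0:
        raise DataError("track has zero mapped reads; RPKM undefined")
    if strand == "+":
        lo, hi = start, end - exclude_last
    elif strand == "-":
        lo, hi = start + exclude_last, end
    else:
        raise DataError(f"invalid strand {strand!r}")
    eff_len = hi - lo
    if eff_len <= 0:
        raise DataError(
            f"effective region length <= 0 after excluding {exclude_last} nt"
        )
    n = track.count_in(chrom, lo, hi, strand)
    return n / (eff_len / 1e3) / (track.total_mapped / 1e6)


@dataclass
class MetageneProfile:
    """Stop-aligned average density over offsets [-w_up, +w_down]."""

    offsets: np.ndarray
    density: np.ndarray
    n_genes: int
    mode: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "density": self.density})

    def value_at(self, offset: int) -> float:
        idx = np.flatnonzero(self.offsets == offset)
        if not len(idx):
            raise DataError(f"offset {offset} outside profile window")
        return float(self.density[idx[0]])


def metagene_stop_profile(
    track: DensityTrack,
    annotation: Annotation,
    w_up: int = 120,
    w_down: int = 150,
    clearance: int = 110,
    min_cds_reads: int = 32,
    mode: str = "gene-normalized",
) -> MetageneProfile:
    """Average 3'-end density across genes aligned at the stop codon.

    Genes enter the profile when (a) no other CDS starts within
    ``clearance`` nt downstream of their stop codon, (b) their CDS carries
    at least ``min_cds_reads`` 3'-end counts, and (c) the whole offset
    window fits on the chromosome.  ``mode='rpm'`` averages plain
    reads-per-million values; ``mode='gene-normalized'`` first divides each
    gene's positional values by that gene's mean CDS density, so every
    gene contributes with equal weight regardless of expression.
    """
    if w_up <= 0 or w_down <= 0:
        raise DataError("metagene windows must be positive")
    if mode not in ("rpm", "gene-normalized"):
        raise DataError(f"unknown metagene mode {mode!r}")
    if track.total_mapped <= 0:
        raise DataError("track has zero mapped reads")
    offsets = np.arange(-w_up, w_down + 1)
    acc = np.zeros(offsets.shape, dtype=float)
    n_genes = 0
    rpm_factor = 1e6 / track.total_mapped
    for g in annotation.genes:
        if not annotation.downstream_clearance(g.gene_id, clearance):
            continue
        arr = track.array(g.chrom, g.strand)
        anchor = g.stop_anchor
        pos = anchor + offsets if g.strand == "+" else anchor - offsets
        if pos.min() < 0 or pos.max() >= len(arr):
            continue
        cds_count = track.count_in(g.chrom, g.cds_start, g.cds_end, g.strand)
        if cds_count < min_cds_reads:
            continue
        vals = arr[pos].astype(float)
        if mode == "rpm":
            acc += vals * rpm_factor
        else:
            acc += vals / (cds_count / g.cds_len)
        n_genes += 1
    if n_genes == 0:
        raise DataError("no gene passes the metagene filters")
    return MetageneProfile(offsets, acc / n_genes, n_genes, mode)


@dataclass
class PeakResult:
    """Stacked-ribosome peaks upstream of the stop codon."""

    peaks: list[tuple[int, float]]  # (offset, height), ascending offset
    modal_spacing: float | None  # median distance between successive peaks


def detect_stacked_peaks(
    profile: MetageneProfile,
    search_window: tuple[int, int] = (-90, -10),
    min_prominence: float = 3.0,
) -> PeakResult:
    """Find local maxima upstream of the anchor and their modal spacing.

    A peak must have prominence at least ``min_prominence`` times the
    median profile value within the search window.  An empty result is a
    valid outcome (no queueing detected).
    """
    lo, hi = search_window
    mask = (profile.offsets >= lo) & (profile.offsets <= hi)
    if not mask.any():
        raise DataError("search window outside profile offsets")
    vals = profile.density[mask]
    offs = profile.offsets[mask]
    med = float(np.median(vals))
    threshold = min_prominence * med if med > 0 else np.finfo(float).tiny
    idx, props = find_peaks(vals, prominence=threshold)
    peaks = [(int(offs[i]), float(vals[i])) for i in idx]
    spacing = None
    if len(peaks) >= 2:
        spacing = float(np.median(np.diff([p[0] for p in peaks])))
    return PeakResult(peaks, spacing)
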