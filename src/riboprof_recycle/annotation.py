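"""Genome annotation: genes, transcript units, 3'-UTRs, gene pairs.

All coordinates are 0-based half-open internally; GFF3's 1-based inclusive
coordinates are converted at the file boundary.  A gene's CDS includes its
stop codon (the last 3 nt).  Transcript units (TUs) are the operonic
transcription spans that define 3'-UTRs and consecutive gene pairs: on the
plus strand the 3'-UTR of the TU-terminal gene is ``[cds_end, tu_end)``, on
the minus strand ``[tu_start, cds_start)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from intervaltree import IntervalTree


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation inputs."""


@dataclass(frozen=True)
class GeneModel:
    """A single protein-coding gene (CDS interval incl. stop codon)."""

    gene_id: str
    chrom: str
    strand: str
    cds_start: int
    cds_end: int
    tu_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not (0 <= self.cds_start < self.cds_end):
            raise AnnotationError(
                f"gene {self.gene_id}: invalid CDS interval "
                f"[{self.cds_start}, {self.cds_end})"
            )
        if self.cds_len < 6:
            raise AnnotationError(
                f"gene {self.gene_id}: CDS of {self.cds_len} nt is shorter than "
                "6 nt (must hold at least one sense codon plus the stop codon)"
            )

    @property
    def cds_len(self) -> int:
        return self.cds_end - self.cds_start

    @property
    def stop_anchor(self) -> int:
        """Genomic position of the final nt of the stop codon."""
        return self.cds_end - 1 if self.strand == "+" else self.cds_start


@dataclass(frozen=True)
class TranscriptUnit:
    """An operonic transcription span holding one or more genes, 5'->3'."""

    tu_id: str
    chrom: str
    strand: str
    tu_start: int
    tu_end: int
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"TU {self.tu_id}: invalid strand {self.strand!r}")
        if not (0 <= self.tu_start < self.tu_end):
            raise AnnotationError(
                f"TU {self.tu_id}: invalid span [{self.tu_start}, {self.tu_end})"
            )
        if not self.gene_ids:
            raise AnnotationError(f"TU {self.tu_id}: no member genes")


class Annotation:
    """Validated gene + transcript-unit annotation with derived intervals.

    Genes without a resolved TU are retained but excluded from 3'-UTR and
    gene-pair analyses.
    """

    def __init__(
        self,
        genes: Iterable[GeneModel],
        tus: Iterable[TranscriptUnit],
        chrom_lengths: dict[str, int],
    ) -> None:
        self._genes: dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in self._genes:
                raise AnnotationError(f"duplicate gene id {g.gene_id}")
            self._genes[g.gene_id] = g
        self._tus: dict[str, TranscriptUnit] = {}
        for tu in tus:
            if tu.tu_id in self._tus:
                raise AnnotationError(f"duplicate TU id {tu.tu_id}")
            self._tus[tu.tu_id] = tu
        self.chrom_lengths = dict(chrom_lengths)
        self._validate()
        self._trees = self._build_cds_trees()

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        for g in self._genes.values():
            if g.chrom not in self.chrom_lengths:
                raise AnnotationError(f"gene {g.gene_id}: unknown chromosome {g.chrom}")
            if g.cds_end > self.chrom_lengths[g.chrom]:
                raise AnnotationError(
                    f"gene {g.gene_id}: CDS extends past end of {g.chrom}"
                )
            if g.tu_id is not None and g.tu_id not in self._tus:
                raise AnnotationError(
                    f"gene {g.gene_id}: references unknown TU {g.tu_id}"
                )
        for tu in self._tus.values():
            prev = None
            for gid in tu.gene_ids:
                if gid not in self._genes:
                    raise AnnotationError(
                        f"transcript unit {tu.tu_id} references unknown gene {gid}"
                    )
                g = self._genes[gid]
                if g.chrom != tu.chrom or g.strand != tu.strand:
                    raise AnnotationError(
                        f"gene {gid} does not match chrom/strand of TU {tu.tu_id}"
                    )
                if g.cds_start < tu.tu_start or g.cds_end > tu.tu_end:
                    raise AnnotationError(
                        f"gene {gid} lies outside the span of TU {tu.tu_id}"
                    )
                if prev is not None:
                    ok = (
                        g.cds_start > prev.cds_start
                        if tu.strand == "+"
                        else g.cds_start < prev.cds_start
                    )
                    if not ok:
                        raise AnnotationError(
                            f"TU {tu.tu_id}: member genes are not ordered 5'->3'"
                        )
                prev = g

    def _build_cds_trees(self) -> dict[str, IntervalTree]:
        trees: dict[str, IntervalTree] = {}
        for g in self._genes.values():
            trees.setdefault(g.chrom, IntervalTree()).addi(
                g.cds_start, g.cds_end, g.gene_id
            )
        return trees

    # -- basic access -------------------------------------------------------

    @property
    def genes(self) -> list[GeneModel]:
        return list(self._genes.values())

    @property
    def tus(self) -> list[TranscriptUnit]:
        return list(self._tus.values())

    @property
    def gene_ids(self) -> list[str]:
        return list(self._genes)

    def gene(self, gene_id: str) -> GeneModel:
        try:
            return self._genes[gene_id]
        except KeyError:
            raise AnnotationError(f"unknown gene id {gene_id}") from None

    def tu(self, tu_id: str) -> TranscriptUnit:
        try:
            return self._tus[tu_id]
        except KeyError:
            raise AnnotationError(f"unknown TU id {tu_id}") from None

    # -- derived intervals --------------------------------------------------

    def is_last_in_tu(self, gene_id: str) -> bool:
        g = self.gene(gene_id)
        if g.tu_id is None:
            return False
        return self.tu(g.tu_id).gene_ids[-1] == gene_id

    def utr3_interval(self, gene_id: str) -> tuple[int, int] | None:
        """3'-UTR of a TU-terminal gene, or None.

        Only the last gene of a TU (in translation direction) owns the TU's
        3'-UTR; internal genes return None, as do genes without a TU and
        TUs whose span ends flush with the CDS.
        """
        g = self.gene(gene_id)
        if g.tu_id is None or not self.is_last_in_tu(gene_id):
            return None
        tu = self.tu(g.tu_id)
        if g.strand == "+":
            iv = (g.cds_end, tu.tu_end)
        else:
            iv = (tu.tu_start, g.cds_start)
        return iv if iv[1] > iv[0] else None

    def intergenic_distance(self, up_id: str, down_id: str) -> tuple[int, bool]:
        """Signed stop-to-start distance between consecutive operon genes.

        Negative distances mean the stop and start codons overlap (e.g. the
        common ATGA arrangement gives -4).
        """
        up, down = self.gene(up_id), self.gene(down_id)
        if up.tu_id is None or up.tu_id != down.tu_id:
            raise AnnotationError(
                f"{up_id} and {down_id} are not members of the same TU"
            )
        ids = self.tu(up.tu_id).gene_ids
        i, j = ids.index(up_id), ids.index(down_id)
        if j != i + 1:
            raise AnnotationError(
                f"{up_id} and {down_id} are not consecutive in TU {up.tu_id}"
            )
        if up.strand == "+":
            dist = down.cds_start - up.cds_end
        else:
            dist = up.cds_start - down.cds_end
        return dist, dist < 0

    def downstream_clearance(self, gene_id: str, window: int) -> bool:
        """True iff no other CDS overlaps the ``window`` nt 3' of the stop."""
        if window < 0:
            raise AnnotationError("clearance window must be >= 0")
        g = self.gene(gene_id)
        if window == 0:
            return True
        if g.strand == "+":
            lo, hi = g.cds_end, g.cds_end + window
        else:
            lo, hi = max(0, g.cds_start - window), g.cds_start
        if hi <= lo:
            return True
        hits = self._trees[g.chrom].overlap(lo, hi)
        return all(h.data == gene_id for h in hits)

    def gene_pairs(self) -> Iterator[tuple[str, str, str]]:
        """Yield (up_gene, down_gene, tu_id) for consecutive genes per TU."""
        for tu in self._tus.values():
            for a, b in zip(tu.gene_ids, tu.gene_ids[1:]):
                yield a, b, tu.tu_id


# -- file loading -----------------------------------------------------------

_TU_COLUMNS = ("tu_id", "chrom", "strand", "tu_start", "tu_end", "gene_ids")


def load_annotation(
    gff3_path: str | Path,
    tu_table_path: str | Path,
    chrom_lengths_path: str | Path | None = None,
    gene_id_attr: str = "ID",
) -> Annotation:
    """Load genes from GFF3 CDS features and TUs from a TSV table.

    The TU table needs columns tu_id, chrom, strand, tu_start, tu_end and
    gene_ids (comma-separated, 5'->3'); an optional ``priority`` column
    resolves genes claimed by several TUs (lowest value wins, mirroring an
    operon-first rule).  Chromosome lengths come from a two-column
    (name, length) TSV; when omitted they are inferred from the annotation.
    """
    import gffutils

    gff3_path = Path(gff3_path)
    try:
        db = gffutils.create_db(
            str(gff3_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # noqa: BLE001 - surface parser context
        raise AnnotationError(f"failed to parse GFF3 {gff3_path}: {exc}") from exc

    raw_genes: dict[str, dict] = {}
    for feat in db.features_of_type("CDS"):
        if gene_id_attr not in feat.attributes:
            raise AnnotationError(
                f"CDS feature at {feat.seqid}:{feat.start}-{feat.end} lacks "
                f"attribute {gene_id_attr!r}"
            )
        gid = feat.attributes[gene_id_attr][0]
        if gid in raw_genes:
            raise AnnotationError(f"duplicate CDS for gene id {gid} in {gff3_path}")
        raw_genes[gid] = {
            "gene_id": gid,
            "chrom": feat.seqid,
            "strand": feat.strand,
            "cds_start": feat.start - 1,  # 1-based inclusive -> 0-based half-open
            "cds_end": feat.end,
        }

    tu_df = pd.read_csv(tu_table_path, sep="\t", dtype=str)
    missing = [c for c in _TU_COLUMNS if c not in tu_df.columns]
    if missing:
        raise AnnotationError(f"TU table missing columns: {', '.join(missing)}")
    if "priority" not in tu_df.columns:
        tu_df["priority"] = "0"

    # Resolve genes assigned to multiple TUs: lowest priority, then file order.
    claim: dict[str, tuple[int, int, str]] = {}
    parsed_rows = []
    for order, row in enumerate(tu_df.itertuples(index=False)):
        try:
            tu_start, tu_end = int(row.tu_start), int(row.tu_end)
            priority = int(row.priority)
        except (TypeError, ValueError) as exc:
            raise AnnotationError(
                f"TU table line {order + 2}: malformed coordinates ({exc})"
            ) from exc
        members = tuple(g.strip() for g in str(row.gene_ids).split(",") if g.strip())
        parsed_rows.append((row.tu_id, row.chrom, row.strand, tu_start, tu_end, members))
        for gid in members:
            if gid not in raw_genes:
                raise AnnotationError(
                    f"transcript unit {row.tu_id} references unknown gene {gid}"
                )
            key = (priority, order, row.tu_id)
            if gid not in claim or key < claim[gid]:
                claim[gid] = key

    tus = []
    for tu_id, chrom, strand, tu_start, tu_end, members in parsed_rows:
        kept = tuple(g for g in members if claim[g][2] == tu_id)
        if kept:
            tus.append(TranscriptUnit(tu_id, chrom, strand, tu_start, tu_end, kept))
    tu_of = {g: key[2] for g, key in claim.items()}
    kept_tus = {tu.tu_id for tu in tus}

    genes = []
    for gid, kw in raw_genes.items():
        tu_id = tu_of.get(gid)
        if tu_id is not None and tu_id not in kept_tus:
            tu_id = None
        genes.append(GeneModel(tu_id=tu_id, **kw))

    if chrom_lengths_path is not None:
        cl = pd.read_csv(
            chrom_lengths_path, sep="\t", header=None, names=["chrom", "length"]
        )
        chrom_lengths = dict(zip(cl["chrom"].astype(str), cl["length"].astype(int)))
    else:
        chrom_lengths = {}
        for g in genes:
            chrom_lengths[g.chrom] = max(chrom_lengths.get(g.chrom, 0), g.cds_end)
        for tu in tus:
            chrom_lengths[tu.chrom] = max(chrom_lengths.get(tu.chrom, 0), tu.tu_end)

    return Annotation(genes, tus, chrom_lengths)


def mirror_annotation(ann: Annotation) -> Annotation:
    """Reverse-complement the whole annotation (coordinates and strands).

    Used to check strand symmetry: analyses must be invariant under this map.
    """
    lengths = ann.chrom_lengths
    flip = {"+": "-", "-": "+"}

    def mg(g: GeneModel) -> GeneModel:
        n = lengths[g.chrom]
        return replace(
            g,
            strand=flip[g.strand],
            cds_start=n - g.cds_end,
            cds_end=n - g.cds_start,
        )

    def mtu(tu: TranscriptUnit) -> TranscriptUnit:
        n = lengths[tu.chrom]
        return TranscriptUnit(
            tu.tu_id,
            tu.chrom,
            flip[tu.strand],
            n - tu.tu_end,
            n - tu.tu_start,
            tu.gene_ids,
        )

    return Annotation([mg(g) for g in ann.genes], [mtu(t) for t in ann.tus], lengths)
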