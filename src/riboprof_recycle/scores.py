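"""Per-gene summary scores and group comparisons.

Definitions (all RPKM-based, with the terminal ``exclude_last`` nt of every
CDS region removed before counting):

* 3'-UTR score: RPKM of the 3'-UTR divided by RPKM of the upstream CDS —
  quantifies post-termination complexes that have escaped into the UTR.
* collision score: RPKM of the last ``last_window`` nt of the CDS divided
  by RPKM of the whole CDS — quantifies ribosome queueing at ORF ends.
* ribosome occupancy (RO): footprint RPKM divided by RNA-seq RPKM — a
  per-gene translation-level proxy used to stratify genes.

Genes with an undefined denominator are excluded rather than pseudocounted.
Group comparisons use the one-sided Mann-Whitney rank-sum test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import Annotation
from .density import DensityTrack, region_rpkm
from .io import DataError


def cds_rpkm(
    track: DensityTrack, annotation: Annotation, gene_id: str, exclude_last: int = 15
) -> float:
    g = annotation.gene(gene_id)
    return region_rpkm(track, g.chrom, g.cds_start, g.cds_end, g.strand, exclude_last)


def utr3_rpkm(
    track: DensityTrack, annotation: Annotation, gene_id: str
) -> float | None:
    utr = annotation.utr3_interval(gene_id)
    if utr is None:
        return None
    g = annotation.gene(gene_id)
    return region_rpkm(track, g.chrom, utr[0], utr[1], g.strand, exclude_last=0)


def utr3_score(
    track: DensityTrack, annotation: Annotation, gene_id: str, exclude_last: int = 15
) -> float | None:
    """3'-UTR RPKM over CDS RPKM; None when no UTR or the CDS is silent."""
    u = utr3_rpkm(track, annotation, gene_id)
    if u is None:
        return None
    c = cds_rpkm(track, annotation, gene_id, exclude_last)
    if c == 0.0:
        return None
    return u / c


def collision_score(
    track: DensityTrack,
    annotation: Annotation,
    gene_id: str,
    exclude_last: int = 15,
    last_window: int = 100,
) -> float | None:
    """Last-``last_window``-nt RPKM over whole-CDS RPKM.

    The terminal ``exclude_last`` nt are removed from numerator and
    denominator alike.  Genes with CDS <= last_window + exclude_last nt
    are skipped (None): the window would cover the whole gene.
    """
    g = annotation.gene(gene_id)
    if g.cds_len <= last_window + exclude_last:
        return None
    if g.strand == "+":
        win = (g.cds_end - last_window, g.cds_end)
    else:
        win = (g.cds_start, g.cds_start + last_window)
    denom = region_rpkm(track, g.chrom, g.cds_start, g.cds_end, g.strand, exclude_last)
    if denom == 0.0:
        return None
    num = region_rpkm(track, g.chrom, win[0], win[1], g.strand, exclude_last)
    return num / denom


def ribosome_occupancy(
    rpf_track: DensityTrack,
    rna_track: DensityTrack,
    annotation: Annotation,
    exclude_last: int = 15,
) -> pd.DataFrame:
    """Per-gene RO = footprint RPKM / RNA RPKM (matched samples).

    Genes with zero RNA RPKM are absent from the output.
    """
    rows = []
    for g in annotation.genes:
        rna = cds_rpkm(rna_track, annotation, g.gene_id, exclude_last)
        if rna == 0.0:
            continue
        rpf = cds_rpkm(rpf_track, annotation, g.gene_id, exclude_last)
        rows.append({"gene_id": g.gene_id, "rpf_rpkm": rpf, "rna_rpkm": rna,
                     "ro": rpf / rna})
    if not rows:
        raise DataError("no gene with nonzero RNA RPKM")
    return pd.DataFrame(rows).set_index("gene_id")


def assign_ro_groups(
    ro: pd.Series, top_frac: float = 0.20, bottom_frac: float = 0.40
) -> pd.Series:
    """Label genes 'high' / 'low' / 'none' by RO quantile rank.

    Quantile thresholds are computed on the supplied (reference-library)
    RO values; propagate the returned labels to other libraries by gene id.
    """
    if ro.empty:
        raise DataError("empty RO series")
    q_hi = float(np.quantile(ro.to_numpy(), 1.0 - top_frac))
    q_lo = float(np.quantile(ro.to_numpy(), bottom_frac))
    labels = pd.Series("none", index=ro.index, name="ro_group")
    labels[ro >= q_hi] = "high"
    labels[ro <= q_lo] = "low"
    return labels


def mann_whitney_one_sided(
    x, y, alternative: str = "less", method: str = "auto"
) -> tuple[float, float]:
    """One-sided Mann-Whitney rank-sum test; returns (U of x, p).

    ``alternative='less'`` tests whether x tends smaller than y (i.e. y
    greater), ``'greater'`` the reverse.  With ``method='auto'`` the
    p-value is exact (full enumeration of the rank distribution) when the
    smaller sample has at most 8 observations and there are no ties;
    otherwise the normal approximation with tie and continuity corrections
    is used.  ``method`` may force either route.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("Mann-Whitney requires two non-empty samples")
    if alternative not in ("less", "greater"):
        raise DataError(f"invalid alternative {alternative!r}")
    if method == "auto":
        combined = np.concatenate([x, y])
        no_ties = np.unique(combined).size == combined.size
        method = "exact" if (min(x.size, y.size) <= 8 and no_ties) else "asymptotic"
    elif method not in ("exact", "asymptotic"):
        raise DataError(f"invalid method {method!r}")
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def gene_score_table(
    rpf_track: DensityTrack,
    annotation: Annotation,
    rna_track: DensityTrack | None = None,
    exclude_last: int = 15,
    last_window: int = 100,
) -> pd.DataFrame:
    """All per-gene scores for one footprint library (NaN where undefined)."""
    rows = []
    for g in annotation.genes:
        c = cds_rpkm(rpf_track, annotation, g.gene_id, exclude_last)
        u = utr3_rpkm(rpf_track, annotation, g.gene_id)
        coll = collision_score(
            rpf_track, annotation, g.gene_id, exclude_last, last_window
        )
        if g.strand == "+":
            last_iv = (g.cds_end - last_window, g.cds_end)
        else:
            last_iv = (g.cds_start, g.cds_start + last_window)
        last_ok = g.cds_len > last_window + exclude_last
        row = {
            "gene_id": g.gene_id,
            "library_id": rpf_track.library_id,
            "cds_rpkm": c,
            "utr3_rpkm": np.nan if u is None else u,
            "last100_rpkm": region_rpkm(
                rpf_track, g.chrom, last_iv[0], last_iv[1], g.strand, exclude_last
            )
            if last_ok
            else np.nan,
            "utr3_score": np.nan if (u is None or c == 0.0) else u / c,
            "collision_score": np.nan if coll is None else coll,
        }
        if rna_track is not None:
            rna = cds_rpkm(rna_track, annotation, g.gene_id, exclude_last)
            row["rna_rpkm"] = rna
            row["ro"] = np.nan if rna == 0.0 else c / rna
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")


def sample_fold_change(
    track_a: DensityTrack,
    track_b: DensityTrack,
    annotation: Annotation,
    min_rpkm: float = 1.0,
    fold_threshold: float = 10.0,
    exclude_last: int = 15,
) -> pd.DataFrame:
    """Per-gene RPKM ratio b/a; genes below ``min_rpkm`` in both are dropped.

    The returned frame carries a boolean ``above_threshold`` column and is
    sorted by descending ratio, so the >= ``fold_threshold`` set reads off
    the top.
    """
    rows = []
    for g in annotation.genes:
        a = cds_rpkm(track_a, annotation, g.gene_id, exclude_last)
        b = cds_rpkm(track_b, annotation, g.gene_id, exclude_last)
        if a < min_rpkm and b < min_rpkm:
            continue
        ratio = np.inf if a == 0.0 else b / a
        rows.append({"gene_id": g.gene_id, "rpkm_a": a, "rpkm_b": b, "ratio": ratio})
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["above_threshold"] = df["ratio"] >= fold_threshold
    return df.sort_values(
        ["ratio", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
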