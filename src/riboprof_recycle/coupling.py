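"""Genome-wide translational-coupling analysis on operon gene pairs.

For every pair of consecutive genes on a polycistronic transcript unit we
compute the ratio of ribosome footprint density (upstream RPKM / downstream
RPKM) in two conditions and compare them: if translation of the downstream
gene depended on recycling at the upstream stop codon, depletion of the
recycling factor should shift these ratios.  Pairs whose RNA abundances
differ by more than ``max_fold`` (default 5) are excluded so that
transcription-level differences within an operon do not masquerade as
coupling changes.  Pairs whose ratio changes at least ``pair_fold``
(default 2) between conditions are classed ``up2x`` / ``down2x``, and the
intergenic-distance distributions of the two classes are compared with a
one-sided Mann-Whitney test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import Annotation
from .density import DensityTrack
from .io import DataError
from .scores import cds_rpkm, mann_whitney_one_sided


def derive_pairs(annotation: Annotation) -> pd.DataFrame:
    """One row per consecutive gene couple in each multi-gene TU (5'->3')."""
    rows = []
    for up, down, tu_id in annotation.gene_pairs():
        dist, overlap = annotation.intergenic_distance(up, down)
        rows.append(
            {
                "up_gene": up,
                "down_gene": down,
                "tu_id": tu_id,
                "intergenic_distance": dist,
                "overlap": overlap,
            }
        )
    return pd.DataFrame(
        rows, columns=["up_gene", "down_gene", "tu_id", "intergenic_distance", "overlap"]
    )


def filter_pairs_by_rna(
    pairs: pd.DataFrame,
    rna_track: DensityTrack,
    annotation: Annotation,
    max_fold: float = 5.0,
    exclude_last: int = 15,
) -> pd.DataFrame:
    """Keep pairs whose RNA abundance ratio lies within [1/max_fold, max_fold].

    The boundary is inclusive (a pair at exactly ``max_fold`` is kept);
    pairs with zero RNA RPKM in either gene are removed.
    """
    if pairs.empty:
        return pairs.assign(rna_ratio=pd.Series(dtype=float))
    rpkm = {
        gid: cds_rpkm(rna_track, annotation, gid, exclude_last)
        for gid in pd.unique(pairs[["up_gene", "down_gene"]].to_numpy().ravel())
    }
    up = pairs["up_gene"].map(rpkm).to_numpy()
    down = pairs["down_gene"].map(rpkm).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(down > 0, up / down, np.nan)
    out = pairs.copy()
    out["rna_ratio"] = ratio
    keep = (up > 0) & (down > 0) & (ratio >= 1.0 / max_fold) & (ratio <= max_fold)
    return out[keep].reset_index(drop=True)


def pair_ratio_table(
    pairs: pd.DataFrame,
    rpf_tracks: dict[str, DensityTrack],
    annotation: Annotation,
    min_rpkm: float = 1.0,
    pair_fold: float = 2.0,
    exclude_last: int = 15,
    reference: str = "WT",
    treatment: str = "KD",
) -> pd.DataFrame:
    """Up/down footprint-density ratios per condition plus the change class.

    Both genes of a pair must reach ``min_rpkm`` in both libraries.  The
    class is ``up2x`` when ratio_treatment / ratio_reference >=
    ``pair_fold``, ``down2x`` when <= 1/pair_fold (boundaries inclusive),
    else ``neutral``.
    """
    for lib in (reference, treatment):
        if lib not in rpf_tracks:
            raise DataError(f"missing footprint track for {lib!r}")
    rows = []
    for rec in pairs.itertuples(index=False):
        vals = {}
        ok = True
        for lib in (reference, treatment):
            u = cds_rpkm(rpf_tracks[lib], annotation, rec.up_gene, exclude_last)
            d = cds_rpkm(rpf_tracks[lib], annotation, rec.down_gene, exclude_last)
            if u < min_rpkm or d < min_rpkm:
                ok = False
                break
            vals[lib] = u / d
        if not ok:
            continue
        r_ref, r_trt = vals[reference], vals[treatment]
        change = r_trt / r_ref
        if change >= pair_fold:
            cls = "up2x"
        elif change <= 1.0 / pair_fold:
            cls = "down2x"
        else:
            cls = "neutral"
        rows.append(
            {
                **rec._asdict(),
                f"ratio_{reference}": r_ref,
                f"ratio_{treatment}": r_trt,
                f"log2_ratio_{reference}": np.log2(r_ref),
                f"log2_ratio_{treatment}": np.log2(r_trt),
                "ratio_change": change,
                "class": cls,
            }
        )
    cols = list(pairs.columns) + [
        f"ratio_{reference}", f"ratio_{treatment}",
        f"log2_ratio_{reference}", f"log2_ratio_{treatment}",
        "ratio_change", "class",
    ]
    return pd.DataFrame(rows, columns=cols)


@dataclass
class CouplingCorrelation:
    r_log2: float
    r_raw: float
    n: int


def correlate_pair_ratios(
    table: pd.DataFrame,
    overlap_only: bool = False,
    reference: str = "WT",
    treatment: str = "KD",
) -> CouplingCorrelation:
    """Pearson correlation of pair ratios between the two conditions.

    The headline value is computed on log2 ratios (the scale on which the
    ratios are naturally symmetric); the raw-scale correlation is also
    reported.  Restrict to stop/start-overlapping pairs with
    ``overlap_only=True``.
    """
    sub = table[table["overlap"]] if overlap_only else table
    if len(sub) < 3:
        raise DataError(f"need >= 3 pairs for a correlation, got {len(sub)}")
    x = sub[f"log2_ratio_{reference}"].to_numpy()
    y = sub[f"log2_ratio_{treatment}"].to_numpy()
    r_log2 = float(np.corrcoef(x, y)[0, 1])
    r_raw = float(
        np.corrcoef(
            sub[f"ratio_{reference}"].to_numpy(), sub[f"ratio_{treatment}"].to_numpy()
        )[0, 1]
    )
    return CouplingCorrelation(r_log2=r_log2, r_raw=r_raw, n=len(sub))


@dataclass
class ClassDistanceResult:
    computable: bool
    n_up2x: int
    n_down2x: int
    u_statistic: float | None
    p_value: float | None
    distances_up2x: np.ndarray
    distances_down2x: np.ndarray


def compare_class_distances(
    table: pd.DataFrame, alternative: str = "greater"
) -> ClassDistanceResult:
    """Compare intergenic distances of up2x vs down2x pairs.

    ``alternative='greater'`` tests whether up2x pairs have longer
    intergenic distances than down2x pairs.  When either class is empty
    the result is flagged not computable instead of raising.
    """
    d_up = table.loc[table["class"] == "up2x", "intergenic_distance"].to_numpy(float)
    d_dn = table.loc[table["class"] == "down2x", "intergenic_distance"].to_numpy(float)
    if len(d_up) == 0 or len(d_dn) == 0:
        return ClassDistanceResult(False, len(d_up), len(d_dn), None, None, d_up, d_dn)
    u, p = mann_whitney_one_sided(d_up, d_dn, alternative=alternative)
    return ClassDistanceResult(True, len(d_up), len(d_dn), u, p, d_up, d_dn)


def distance_histogram(
    distances: np.ndarray, bin_width: int = 5
) -> pd.DataFrame:
    """Histogram counts of intergenic distances with fixed-width bins."""
    if len(distances) == 0:
        return pd.DataFrame(columns=["bin_start", "bin_end", "count"])
    lo = int(np.floor(distances.min() / bin_width) * bin_width)
    hi = int(np.ceil((distances.max() + 1) / bin_width) * bin_width)
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, _ = np.histogram(distances, bins=edges)
    return pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts}
    )
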