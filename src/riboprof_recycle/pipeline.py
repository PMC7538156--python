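"""End-to-end orchestration: simulation/inputs -> tracks -> scores -> report.

A run produces, per footprint library: bedGraph tracks, a stop-codon
metagene profile, a stacked-peak table and a per-gene score table; and
across libraries: the high-salt 3'-UTR comparison, occupancy-stratified
score comparisons, the operon pair-ratio table with its correlation
summary, and the between-strain fold-change table.  Identical
configuration + seed reproduce every output byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotation import Annotation, load_annotation
from .config import GENOTYPES, TIME_POINTS, RunConfig
from .coupling import (
    compare_class_distances,
    correlate_pair_ratios,
    derive_pairs,
    distance_histogram,
    filter_pairs_by_rna,
    pair_ratio_table,
)
from .density import build_density_track, detect_stacked_peaks, metagene_stop_profile
from .io import (
    DataError,
    read_bed6,
    write_bed6,
    write_bedgraph,
    write_chrom_lengths,
    write_gff3,
    write_tsv,
    write_tu_table,
)
from .scores import (
    assign_ro_groups,
    gene_score_table,
    mann_whitney_one_sided,
    ribosome_occupancy,
    sample_fold_change,
)
from .synthetic import generate_annotation, library_id, simulate_sample

log = logging.getLogger("riboprof_recycle")

FOOTPRINT_PREPS = ("standard", "salt")


def all_conditions() -> list[tuple[str, int, str]]:
    return [
        (g, t, p)
        for g in GENOTYPES
        for t in TIME_POINTS
        for p in ("standard", "salt", "rna")
    ]


def _ensure_dirs(out: Path) -> dict[str, Path]:
    dirs = {name: out / name for name in ("reads", "tracks", "tables")}
    for d in dirs.values():
        d.mkdir(parents=True, exist_ok=True)
    return dirs


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full analysis; returns a map of output names to paths."""
    config.validate()
    out = Path(config.out_dir)
    dirs = _ensure_dirs(out)
    outputs: dict[str, Path] = {}

    echo = config.to_json()
    (out / "config.json").write_text(echo)
    outputs["config"] = out / "config.json"

    # -- stage: inputs ------------------------------------------------------
    if config.simulate:
        log.info("simulating annotation and %d libraries", len(all_conditions()))
        ann = generate_annotation(config.sim, seed=config.seed)
        write_gff3(ann, out / "annotation.gff3")
        write_tu_table(ann, out / "transcript_units.tsv")
        write_chrom_lengths(ann, out / "chrom_lengths.tsv")
        truth = None
        reads = {}
        for cond in all_conditions():
            lib = library_id(cond)
            lib_reads, truth = simulate_sample(
                ann, truth, config.sim, cond, seed=config.seed
            )
            write_bed6(lib_reads, dirs["reads"] / f"{lib}.bed")
            reads[lib] = lib_reads
        write_tsv(truth.to_frame(), out / "sim_truth.tsv")
        outputs["truth"] = out / "sim_truth.tsv"
    else:
        ann = load_annotation(
            config.annotation_gff3, config.tu_table, config.chrom_lengths
        )
        reads = {lib: read_bed6(path) for lib, path in config.reads.items()}
        if not reads:
            raise DataError("no read libraries configured")

    # -- stage: tracks ------------------------------------------------------
    tracks = {}
    for lib, lib_reads in reads.items():
        tracks[lib] = build_density_track(lib_reads, ann, library_id=lib)
        write_bedgraph(tracks[lib], dirs["tracks"] / lib)

    def lib_of(genotype: str, t: int, prep: str) -> str:
        return f"{genotype}_{t}_{prep}"

    def has(genotype: str, t: int, prep: str) -> bool:
        return lib_of(genotype, t, prep) in tracks

    # -- stage: metagenes and per-library scores ----------------------------
    peak_rows = []
    for lib, track in sorted(tracks.items()):
        if lib.endswith("_rna"):
            continue
        try:
            profile = metagene_stop_profile(
                track,
                ann,
                w_up=config.w_up,
                w_down=config.w_down,
                clearance=config.clearance,
                min_cds_reads=config.min_cds_reads,
                mode=config.metagene_mode,
            )
        except DataError as exc:
            log.warning("metagene skipped for %s: %s", lib, exc)
            continue
        write_tsv(profile.to_frame(), dirs["tables"] / f"metagene_{lib}.tsv")
        peaks = detect_stacked_peaks(
            profile,
            search_window=(config.peak_search_lo, config.peak_search_hi),
            min_prominence=config.min_prominence,
        )
        for off, height in peaks.peaks:
            peak_rows.append(
                {
                    "library_id": lib,
                    "offset": off,
                    "height": height,
                    "modal_spacing": peaks.modal_spacing,
                    "n_genes": profile.n_genes,
                }
            )
        rna_lib = lib.rsplit("_", 1)[0] + "_rna"
        scores = gene_score_table(
            track,
            ann,
            rna_track=tracks.get(rna_lib),
            exclude_last=config.exclude_last,
            last_window=config.last_window,
        )
        write_tsv(scores.reset_index(), dirs["tables"] / f"scores_{lib}.tsv")
    write_tsv(
        pd.DataFrame(
            peak_rows,
            columns=["library_id", "offset", "height", "modal_spacing", "n_genes"],
        ),
        dirs["tables"] / "stacked_peaks.tsv",
    )
    outputs["stacked_peaks"] = dirs["tables"] / "stacked_peaks.tsv"

    # -- stage: high-salt comparison ----------------------------------------
    salt_rows = []
    for genotype in GENOTYPES:
        for t in TIME_POINTS:
            if not (has(genotype, t, "standard") and has(genotype, t, "salt")):
                continue
            std = tracks[lib_of(genotype, t, "standard")]
            salt = tracks[lib_of(genotype, t, "salt")]
            ratios = []
            from .scores import utr3_score

            for g in ann.genes:
                s_std = utr3_score(std, ann, g.gene_id, config.exclude_last)
                s_salt = utr3_score(salt, ann, g.gene_id, config.exclude_last)
                if s_std is None or s_salt is None or s_std == 0.0:
                    continue
                ratios.append(
                    {
                        "gene_id": g.gene_id,
                        "utr3_score_standard": s_std,
                        "utr3_score_salt": s_salt,
                        "fold_reduction": np.inf if s_salt == 0 else s_std / s_salt,
                    }
                )
            if not ratios:
                continue
            df = pd.DataFrame(ratios)
            med_std = float(df["utr3_score_standard"].median())
            med_salt = float(df["utr3_score_salt"].median())
            salt_rows.append(
                {
                    "genotype": genotype,
                    "time_min": t,
                    "n_genes": len(df),
                    "median_of_gene_fold_reductions": float(
                        df["fold_reduction"].median()
                    ),
                    "ratio_of_median_scores": np.inf
                    if med_salt == 0
                    else med_std / med_salt,
                }
            )
            write_tsv(
                df, dirs["tables"] / f"salt_per_gene_{genotype}_{t}.tsv"
            )
    write_tsv(
        pd.DataFrame(
            salt_rows,
            columns=[
                "genotype", "time_min", "n_genes",
                "median_of_gene_fold_reductions", "ratio_of_median_scores",
            ],
        ),
        dirs["tables"] / "salt_comparison.tsv",
    )
    outputs["salt_comparison"] = dirs["tables"] / "salt_comparison.tsv"

    # -- stage: occupancy stratification ------------------------------------
    ref_t = TIME_POINTS[0]
    group_rows = []
    if has("WT", ref_t, "standard") and has("WT", ref_t, "rna"):
        ro = ribosome_occupancy(
            tracks[lib_of("WT", ref_t, "standard")],
            tracks[lib_of("WT", ref_t, "rna")],
            ann,
            config.exclude_last,
        )
        groups = assign_ro_groups(ro["ro"], config.top_frac, config.bottom_frac)
        write_tsv(
            ro.assign(ro_group=groups).reset_index(),
            dirs["tables"] / "ro_reference.tsv",
        )
        for t in TIME_POINTS:
            if not has("KD", t, "standard"):
                continue
            scores = gene_score_table(
                tracks[lib_of("KD", t, "standard")],
                ann,
                exclude_last=config.exclude_last,
                last_window=config.last_window,
            )
            scores = scores.join(groups, how="inner")
            for col, alternative in (("collision_score", "greater"),
                                     ("utr3_score", "less")):
                hi = scores.loc[scores["ro_group"] == "high", col].dropna()
                lo = scores.loc[scores["ro_group"] == "low", col].dropna()
                if hi.empty or lo.empty:
                    continue
                u, p = mann_whitney_one_sided(hi, lo, alternative=alternative)
                group_rows.append(
                    {
                        "time_min": t,
                        "score": col,
                        "alternative": f"high {alternative} than low",
                        "n_high": len(hi),
                        "n_low": len(lo),
                        "median_high": float(hi.median()),
                        "median_low": float(lo.median()),
                        "U": u,
                        "p_value": p,
                    }
                )
    write_tsv(
        pd.DataFrame(
            group_rows,
            columns=["time_min", "score", "alternative", "n_high", "n_low",
                     "median_high", "median_low", "U", "p_value"],
        ),
        dirs["tables"] / "ro_group_comparison.tsv",
    )
    outputs["ro_group_comparison"] = dirs["tables"] / "ro_group_comparison.tsv"

    # -- stage: coupling -----------------------------------------------------
    pair_t = TIME_POINTS[-1]
    if (
        has("WT", pair_t, "standard")
        and has("KD", pair_t, "standard")
        and has("WT", pair_t, "rna")
    ):
        pairs = derive_pairs(ann)
        pairs = filter_pairs_by_rna(
            pairs,
            tracks[lib_of("WT", pair_t, "rna")],
            ann,
            max_fold=config.rna_max_fold,
            exclude_last=config.exclude_last,
        )
        table = pair_ratio_table(
            pairs,
            {
                "WT": tracks[lib_of("WT", pair_t, "standard")],
                "KD": tracks[lib_of("KD", pair_t, "standard")],
            },
            ann,
            min_rpkm=config.min_rpkm,
            pair_fold=config.pair_fold,
            exclude_last=config.exclude_last,
        )
        write_tsv(table, dirs["tables"] / "pair_ratios.tsv")
        outputs["pair_ratios"] = dirs["tables"] / "pair_ratios.tsv"
        summary: dict[str, object] = {"time_min": pair_t, "n_pairs": len(table)}
        if len(table) >= 3:
            corr = correlate_pair_ratios(table)
            summary.update(
                pearson_r_log2=corr.r_log2, pearson_r_raw=corr.r_raw
            )
            if int(table["overlap"].sum()) >= 3:
                oc = correlate_pair_ratios(table, overlap_only=True)
                summary.update(
                    pearson_r_log2_overlap=oc.r_log2, n_overlap_pairs=oc.n
                )
        cls = compare_class_distances(table)
        summary.update(
            n_up2x=cls.n_up2x,
            n_down2x=cls.n_down2x,
            distance_test_p=cls.p_value if cls.computable else np.nan,
        )
        write_tsv(
            pd.DataFrame([summary]), dirs["tables"] / "coupling_summary.tsv"
        )
        outputs["coupling_summary"] = dirs["tables"] / "coupling_summary.tsv"
        for name, arr in (
            ("up2x", cls.distances_up2x),
            ("down2x", cls.distances_down2x),
        ):
            write_tsv(
                distance_histogram(arr),
                dirs["tables"] / f"distance_hist_{name}.tsv",
            )

    # -- stage: fold changes -------------------------------------------------
    if has("WT", pair_t, "standard") and has("KD", pair_t, "standard"):
        fc = sample_fold_change(
            tracks[lib_of("WT", pair_t, "standard")],
            tracks[lib_of("KD", pair_t, "standard")],
            ann,
            min_rpkm=config.min_rpkm,
            fold_threshold=config.fc_threshold,
            exclude_last=config.exclude_last,
        )
        write_tsv(fc, dirs["tables"] / "fold_change.tsv")
        outputs["fold_change"] = dirs["tables"] / "fold_change.tsv"

    manifest = {
        "config_sha256": hashlib.sha256(echo.encode()).hexdigest(),
        "seed": config.seed,
        "version": __version__,
        "outputs": sorted(str(p.relative_to(out)) for p in outputs.values()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    outputs["manifest"] = out / "manifest.json"
    return outputs
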