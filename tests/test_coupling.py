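"""Operon gene-pair derivation, RNA filtering, ratio classes, correlation."""

import numpy as np
import pandas as pd
import pytest

import riboprof_recycle as rr
from riboprof_recycle.annotation import Annotation, GeneModel, TranscriptUnit
from riboprof_recycle.config import SimConfig
from riboprof_recycle.coupling import (
    compare_class_distances,
    correlate_pair_ratios,
    derive_pairs,
    distance_histogram,
    filter_pairs_by_rna,
    pair_ratio_table,
)
from riboprof_recycle.density import DensityTrack, build_density_track
from riboprof_recycle.io import DataError


@pytest.fixture
def pair_annotation():
    """Three equal-length plus-strand genes in one TU plus a singleton."""
    genes = [
        GeneModel("u", "c", "+", 100, 700, "t"),
        GeneModel("m", "c", "+", 720, 1320, "t"),
        GeneModel("d", "c", "+", 1340, 1940, "t"),
        GeneModel("solo", "c", "+", 2100, 2700, "s"),
    ]
    tus = [
        TranscriptUnit("t", "c", "+", 80, 2000, ("u", "m", "d")),
        TranscriptUnit("s", "c", "+", 2080, 2750, ("solo",)),
    ]
    return Annotation(genes, tus, {"c": 3000})


def _uniform_track(ann, per_gene_density, total=1_000_000):
    n = ann.chrom_lengths["c"]
    counts = {("c", "+"): np.zeros(n, np.int64), ("c", "-"): np.zeros(n, np.int64)}
    for gid, dens in per_gene_density.items():
        g = ann.gene(gid)
        counts[(g.chrom, g.strand)][g.cds_start:g.cds_end] = dens
    return DensityTrack(counts, total_mapped=total)


def test_derive_pairs_counts(pair_annotation):
    pairs = derive_pairs(pair_annotation)
    assert len(pairs) == 2  # 3-gene TU -> 2 pairs, singleton -> 0
    assert list(pairs["up_gene"]) == ["u", "m"]
    assert not pairs["overlap"].any()


def test_pair_count_conservation():
    cfg = SimConfig(n_genes=300)
    ann = rr.generate_annotation(cfg, seed=13)
    expected = sum(max(0, len(tu.gene_ids) - 1) for tu in ann.tus)
    assert len(derive_pairs(ann)) == expected


def test_overlapping_pair_flag():
    genes = [
        GeneModel("a", "c", "+", 100, 400, "t"),
        GeneModel("b", "c", "+", 396, 696, "t"),
    ]
    tus = [TranscriptUnit("t", "c", "+", 80, 760, ("a", "b"))]
    ann = Annotation(genes, tus, {"c": 1000})
    pairs = derive_pairs(ann)
    assert len(pairs) == 1
    assert pairs.loc[0, "intergenic_distance"] == -4
    assert bool(pairs.loc[0, "overlap"])


@pytest.mark.parametrize(
    "down_density, kept",
    [(4, True), (2, True), (20, True), (24, False)],  # ratios 1, 2, 1/5, 1/6
)
def test_rna_filter_boundary_is_inclusive(pair_annotation, down_density, kept):
    pairs = derive_pairs(pair_annotation).iloc[:1]
    rna = _uniform_track(pair_annotation, {"u": 4, "m": down_density})
    out = filter_pairs_by_rna(pairs, rna, pair_annotation, max_fold=5.0)
    assert (len(out) == 1) is kept


def test_rna_filter_drops_silent_genes(pair_annotation):
    pairs = derive_pairs(pair_annotation).iloc[:1]
    rna = _uniform_track(pair_annotation, {"u": 4, "m": 0})
    assert len(filter_pairs_by_rna(pairs, rna, pair_annotation)) == 0


def test_pair_ratio_classes(pair_annotation):
    pairs = derive_pairs(pair_annotation)
    wt = _uniform_track(pair_annotation, {"u": 10, "m": 10, "d": 10})
    kd_same = _uniform_track(pair_annotation, {"u": 10, "m": 10, "d": 10})
    table = pair_ratio_table(pairs, {"WT": wt, "KD": kd_same}, pair_annotation)
    assert np.allclose(table["ratio_WT"], 1.0)
    assert (table["class"] == "neutral").all()
    # doubling the upstream density in KD puts the first pair exactly on the
    # inclusive up2x boundary
    kd_up = _uniform_track(pair_annotation, {"u": 20, "m": 10, "d": 10})
    table = pair_ratio_table(pairs, {"WT": wt, "KD": kd_up}, pair_annotation)
    assert table.loc[0, "class"] == "up2x"
    assert table.loc[0, "ratio_change"] == pytest.approx(2.0)


def test_min_rpkm_excludes_weak_pairs(pair_annotation):
    pairs = derive_pairs(pair_annotation)
    wt = _uniform_track(pair_annotation, {"u": 10, "m": 10, "d": 10})
    kd = _uniform_track(pair_annotation, {"u": 10, "m": 0, "d": 10})
    table = pair_ratio_table(pairs, {"WT": wt, "KD": kd}, pair_annotation)
    assert len(table) == 0  # both pairs involve the silent middle gene


def test_correlation_identity_and_antiidentity(pair_annotation):
    base = {
        "overlap": [False, False, True, False],
        "intergenic_distance": [10, 20, -4, 30],
    }
    ratios = np.array([0.5, 1.0, 2.0, 4.0])
    table = pd.DataFrame(
        {
            **base,
            "ratio_WT": ratios,
            "ratio_KD": ratios,
            "log2_ratio_WT": np.log2(ratios),
            "log2_ratio_KD": np.log2(ratios),
        }
    )
    corr = correlate_pair_ratios(table)
    assert corr.r_log2 == pytest.approx(1.0)
    table["ratio_KD"] = 1.0 / ratios
    table["log2_ratio_KD"] = -np.log2(ratios)
    assert correlate_pair_ratios(table).r_log2 == pytest.approx(-1.0)
    with pytest.raises(DataError):
        correlate_pair_ratios(table.iloc[:2])


def test_swapping_libraries_exchanges_classes(pair_annotation):
    pairs = derive_pairs(pair_annotation)
    wt = _uniform_track(pair_annotation, {"u": 10, "m": 10, "d": 10})
    kd = _uniform_track(pair_annotation, {"u": 30, "m": 10, "d": 4})
    fwd = pair_ratio_table(pairs, {"WT": wt, "KD": kd}, pair_annotation)
    rev = pair_ratio_table(pairs, {"WT": kd, "KD": wt}, pair_annotation)
    counts_fwd = fwd["class"].value_counts()
    counts_rev = rev["class"].value_counts()
    assert counts_fwd.get("up2x", 0) == counts_rev.get("down2x", 0)
    assert counts_fwd.get("down2x", 0) == counts_rev.get("up2x", 0)


def _class_table(up_dists, down_dists):
    rows = [
        {"intergenic_distance": d, "class": "up2x"} for d in up_dists
    ] + [{"intergenic_distance": d, "class": "down2x"} for d in down_dists]
    return pd.DataFrame(rows)


class TestClassDistances:
    def test_identical_distributions_not_significant(self):
        d = [5, 10, 15, 20, 25] * 4
        res = compare_class_distances(_class_table(d, list(d)))
        assert res.computable
        assert res.p_value >= 0.5

    def test_extreme_separation(self):
        res = compare_class_distances(_class_table([100] * 20, [5] * 20))
        assert res.p_value < 1e-6

    def test_empty_class_flagged(self):
        res = compare_class_distances(_class_table([10, 20], []))
        assert not res.computable
        assert res.p_value is None

    def test_histogram_bins(self):
        hist = distance_histogram(np.array([-4, -4, 1, 6, 12]), bin_width=5)
        assert hist["count"].sum() == 5
        assert (hist["bin_end"] - hist["bin_start"] == 5).all()


def test_engineered_coupling_is_detected():
    """With downstream-gene occupancy perturbed 2x in the depleted strain,
    the pair-ratio correlation collapses relative to the neutral run."""
    base = dict(n_genes=150)
    results = {}
    for label, strength in (("neutral", 0.0), ("coupled", 1.0)):
        cfg = SimConfig(**base, coupling_strength=strength)
        ann = rr.generate_annotation(cfg, seed=17)
        wt, truth = rr.simulate_sample(ann, None, cfg, ("WT", 60, "standard"), seed=17)
        kd, truth = rr.simulate_sample(ann, truth, cfg, ("KD", 60, "standard"), seed=17)
        rna, _ = rr.simulate_sample(ann, truth, cfg, ("WT", 60, "rna"), seed=17)
        pairs = filter_pairs_by_rna(
            derive_pairs(ann), build_density_track(rna, ann), ann
        )
        table = pair_ratio_table(
            pairs,
            {"WT": build_density_track(wt, ann), "KD": build_density_track(kd, ann)},
            ann,
        )
        results[label] = (
            correlate_pair_ratios(table).r_log2,
            (table["class"] != "neutral").mean(),
        )
    r_neutral, frac_neutral = results["neutral"]
    r_coupled, frac_coupled = results["coupled"]
    assert r_coupled < 0.95 < r_neutral
    assert frac_coupled > frac_neutral + 0.3
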