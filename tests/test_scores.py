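"""Per-gene scores, RO stratification, rank-sum test, fold changes."""

import numpy as np
import pandas as pd
import pytest

import riboprof_recycle as rr
from riboprof_recycle.annotation import Annotation, GeneModel, TranscriptUnit
from riboprof_recycle.config import SimConfig
from riboprof_recycle.density import DensityTrack, build_density_track
from riboprof_recycle.io import DataError
from riboprof_recycle.scores import (
    assign_ro_groups,
    collision_score,
    gene_score_table,
    mann_whitney_one_sided,
    ribosome_occupancy,
    sample_fold_change,
    utr3_score,
)
from conftest import oracle_mw_exact_p, oracle_mw_permutation_p, oracle_rpkm


@pytest.fixture
def long_gene_annotation():
    """One 1000-nt plus-strand gene with a 200-nt 3'-UTR."""
    genes = [GeneModel("g1", "c", "+", 100, 1100, "t1")]
    tus = [TranscriptUnit("t1", "c", "+", 80, 1300, ("g1",))]
    return Annotation(genes, tus, {"c": 1500})


def _track(ann, plus_counts, total=None):
    n = ann.chrom_lengths["c"]
    counts = {("c", "+"): np.zeros(n, np.int64), ("c", "-"): np.zeros(n, np.int64)}
    for pos, c in plus_counts.items():
        counts[("c", "+")][pos] = c
    track = DensityTrack(counts, total_mapped=total or sum(plus_counts.values()))
    return track


class TestUtr3Score:
    def test_equal_density_gives_one(self, long_gene_annotation):
        track = _track(long_gene_annotation, {p: 2 for p in range(100, 1300)})
        assert utr3_score(track, long_gene_annotation, "g1") == pytest.approx(1.0)

    def test_zero_utr_reads_gives_zero(self, long_gene_annotation):
        track = _track(long_gene_annotation, {p: 1 for p in range(100, 1100)})
        assert utr3_score(track, long_gene_annotation, "g1") == 0.0

    def test_silent_cds_is_excluded(self, long_gene_annotation):
        track = _track(long_gene_annotation, {1200: 5})
        assert utr3_score(track, long_gene_annotation, "g1") is None

    def test_no_utr_gene_is_excluded(self, toy_annotation):
        track = _track(toy_annotation, {150: 1})
        assert utr3_score(track, toy_annotation, "ga1") is None


class TestCollisionScore:
    def test_uniform_density_gives_one(self, long_gene_annotation):
        track = _track(long_gene_annotation, {p: 3 for p in range(100, 1100)})
        assert collision_score(track, long_gene_annotation, "g1") == pytest.approx(1.0)

    def test_terminal_window_pileup(self, long_gene_annotation):
        # 1000-nt CDS, all n reads inside [end-100, end-15): (n/85)/(n/985)
        track = _track(long_gene_annotation, {p: 1 for p in range(1000, 1085)})
        expected = (85 / 85) / (85 / 985)
        got = collision_score(track, long_gene_annotation, "g1")
        assert got == pytest.approx(expected)
        assert got == pytest.approx(11.588, abs=1e-3)

    def test_short_cds_is_skipped(self, toy_annotation):
        # gx is only 60 nt long
        track = _track(toy_annotation, {2910: 5})
        assert collision_score(track, toy_annotation, "gx") is None

    def test_matches_per_read_oracle(self, sim40):
        _, ann, libs, _ = sim40
        reads = libs["standard"]
        track = build_density_track(reads, ann, "std")
        for g in ann.genes[:6]:
            got = collision_score(track, ann, g.gene_id)
            if g.cds_len <= 115:
                assert got is None
                continue
            if g.strand == "+":
                win = (g.cds_end - 100, g.cds_end)
            else:
                win = (g.cds_start, g.cds_start + 100)
            num = oracle_rpkm(reads, g.chrom, win[0], win[1], g.strand, 15)
            den = oracle_rpkm(reads, g.chrom, g.cds_start, g.cds_end, g.strand, 15)
            assert got == pytest.approx(num / den, rel=1e-12)


class TestMannWhitney:
    def test_exact_textbook_example(self):
        u, p = mann_whitney_one_sided([1, 2, 3], [4, 5, 6], alternative="less")
        assert u == 0.0
        assert p == pytest.approx(1 / 20)

    def test_identical_samples_not_significant(self):
        x = [1.0, 2.0, 2.0, 3.0, 5.0]
        _, p = mann_whitney_one_sided(x, list(x), alternative="less")
        assert p >= 0.5

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 5)
        y = rng.normal(0.8, 1, 5)
        _, p = mann_whitney_one_sided(x, y, alternative="less")
        assert p == pytest.approx(oracle_mw_exact_p(x, y, "less"), rel=1e-12)

    def test_asymptotic_close_to_permutation_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0.0, 1.0, 8)
        y = rng.normal(1.0, 1.0, 8)
        _, p_approx = mann_whitney_one_sided(x, y, "less", method="asymptotic")
        p_perm = oracle_mw_permutation_p(x, y, "less", n_perm=10_000, seed=11)
        assert abs(p_approx - p_perm) / p_perm < 0.10

    def test_large_shift_is_overwhelming(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 50)
        y = x + 10.0
        _, p = mann_whitney_one_sided(x, y, alternative="less")
        assert p < 1e-6

    def test_empty_sample_rejected(self):
        with pytest.raises(DataError):
            mann_whitney_one_sided([], [1.0])


class TestRibosomeOccupancy:
    def test_quantile_stratification(self):
        ro = pd.Series(np.arange(1.0, 11.0), index=[f"g{i}" for i in range(10)])
        groups = assign_ro_groups(ro, top_frac=0.20, bottom_frac=0.40)
        assert set(ro.index[groups == "high"]) == {"g8", "g9"}
        assert set(ro.index[groups == "low"]) == {"g0", "g1", "g2", "g3"}

    def test_zero_rna_gene_absent(self, long_gene_annotation):
        rpf = _track(long_gene_annotation, {p: 1 for p in range(100, 1100)})
        rna = _track(long_gene_annotation, {2: 1})  # nothing on the gene
        with pytest.raises(DataError):
            ribosome_occupancy(rpf, rna, long_gene_annotation)

    def test_recovers_true_occupancy(self, sim40):
        from scipy.stats import spearmanr

        cfg, ann, libs, truth = sim40
        rna, _ = rr.simulate_sample(ann, truth, cfg, ("KD", 5, "rna"), seed=7)
        ro = ribosome_occupancy(
            build_density_track(libs["standard"], ann),
            build_density_track(rna, ann),
            ann,
        )
        joined = ro.join(truth.genes)
        rho = spearmanr(joined["ro"], joined["o"]).statistic
        assert rho > 0.8


def test_scores_scale_invariant_to_library_size(sim40):
    _, ann, libs, _ = sim40
    track = build_density_track(libs["standard"], ann, "std")
    a = gene_score_table(track, ann)
    b = gene_score_table(track.scaled(13), ann)
    for col in ("utr3_score", "collision_score"):
        pd.testing.assert_series_equal(a[col], b[col])


class TestFoldChange:
    def test_identical_tracks_are_neutral(self, sim40):
        _, ann, libs, _ = sim40
        track = build_density_track(libs["standard"], ann, "std")
        fc = sample_fold_change(track, track, ann)
        assert np.allclose(fc["ratio"], 1.0)
        assert not fc["above_threshold"].any()

    def test_spiked_genes_are_recovered(self):
        # the spiked set must stay small relative to the transcriptome,
        # otherwise it inflates the RPKM denominator of library b
        cfg = SimConfig(n_genes=2000, depth_rpf=0.3)
        ann = rr.generate_annotation(cfg, seed=9)
        _, truth = rr.simulate_sample(ann, None, cfg, ("WT", 5, "standard"), seed=9)
        spiked = sorted(truth.genes.index[:20])
        truth_b = rr.SimTruth(truth.genes.copy())
        truth_b.genes.loc[spiked, "m"] *= 16.0
        reads_a, _ = rr.simulate_sample(ann, truth, cfg, ("WT", 5, "standard"), seed=9)
        reads_b, _ = rr.simulate_sample(ann, truth_b, cfg, ("WT", 5, "standard"), seed=10)
        fc = sample_fold_change(
            build_density_track(reads_a, ann),
            build_density_track(reads_b, ann),
            ann,
            fold_threshold=10.0,
        )
        called = set(fc.loc[fc["above_threshold"], "gene_id"])
        assert called == set(spiked)
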