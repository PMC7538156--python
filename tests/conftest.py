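"""Shared fixtures: a hand-built toy annotation and small simulated runs.

Also hosts the brute-force per-read oracles used to cross-check RPKM and
score computations independently of the vectorised implementation.
"""

from __future__ import annotations

import numpy as np
import pytest

import riboprof_recycle as rr
from riboprof_recycle.annotation import Annotation, GeneModel, TranscriptUnit
from riboprof_recycle.config import SimConfig


@pytest.fixture
def toy_annotation() -> Annotation:
    """Two-TU toy genome: a plus-strand pair, a minus-strand pair with an
    overlap, a single-gene TU and one TU-less gene."""
    genes = [
        GeneModel("ga1", "c", "+", 100, 400, "tuA"),
        GeneModel("ga2", "c", "+", 415, 715, "tuA"),
        GeneModel("gb1", "c", "-", 2000, 2300, "tuB"),
        GeneModel("gb2", "c", "-", 1600, 1996, "tuB"),
        GeneModel("gc1", "c", "+", 2500, 2800, "tuC"),
        GeneModel("gx", "c", "+", 2900, 2960, None),
    ]
    tus = [
        TranscriptUnit("tuA", "c", "+", 80, 800, ("ga1", "ga2")),
        TranscriptUnit("tuB", "c", "-", 1500, 2400, ("gb1", "gb2")),
        TranscriptUnit("tuC", "c", "+", 2480, 2850, ("gc1",)),
    ]
    return Annotation(genes, tus, {"c": 3200})


@pytest.fixture(scope="session")
def sim40():
    """A 40-gene simulated run: annotation, depleted 5-min libraries, truth."""
    cfg = SimConfig(n_genes=40)
    ann = rr.generate_annotation(cfg, seed=7)
    std, truth = rr.simulate_sample(ann, None, cfg, ("KD", 5, "standard"), seed=7)
    salt, _ = rr.simulate_sample(ann, truth, cfg, ("KD", 5, "salt"), seed=7)
    return cfg, ann, {"standard": std, "salt": salt}, truth


# -- brute-force oracles ----------------------------------------------------


def oracle_three_prime(row) -> int:
    return row.end - 1 if row.strand == "+" else row.start


def oracle_region_count(reads, chrom, start, end, strand, exclude_last=0) -> int:
    """Per-read loop: count 3' ends inside a strand-aware trimmed interval."""
    if strand == "+":
        lo, hi = start, end - exclude_last
    else:
        lo, hi = start + exclude_last, end
    n = 0
    for row in reads.itertuples(index=False):
        if row.chrom != chrom or row.strand != strand:
            continue
        if lo <= oracle_three_prime(row) < hi:
            n += 1
    return n


def oracle_rpkm(reads, chrom, start, end, strand, exclude_last=0) -> float:
    if strand == "+":
        eff = (end - exclude_last) - start
    else:
        eff = end - (start + exclude_last)
    n = oracle_region_count(reads, chrom, start, end, strand, exclude_last)
    return n / (eff / 1e3) / (len(reads) / 1e6)


def oracle_mw_exact_p(x, y, alternative="less") -> float:
    """Exact one-sided Mann-Whitney p by full enumeration (tie-free)."""
    from itertools import combinations

    x, y = list(x), list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    nx = len(x)
    u_obs = sum(ranks[v] for v in x) - nx * (nx + 1) / 2
    us = []
    for comb in combinations(range(len(pooled)), nx):
        r = sum(c + 1 for c in comb)
        us.append(r - nx * (nx + 1) / 2)
    us = np.array(us)
    if alternative == "less":
        return float((us <= u_obs).mean())
    return float((us >= u_obs).mean())


def oracle_mw_permutation_p(x, y, alternative="less", n_perm=10_000, seed=0):
    """Permutation estimate of the one-sided Mann-Whitney p-value."""
    from scipy.stats import rankdata

    rng = np.random.default_rng(seed)
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    nx = len(x)

    def u_of(idx):
        ranks = rankdata(pooled)
        return ranks[idx].sum() - nx * (nx + 1) / 2

    obs = u_of(np.arange(nx))
    hits = 0
    for _ in range(n_perm):
        idx = rng.permutation(len(pooled))[:nx]
        u = u_of(idx)
        if (alternative == "less" and u <= obs) or (
            alternative == "greater" and u >= obs
        ):
            hits += 1
    return (hits + 1) / (n_perm + 1)
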