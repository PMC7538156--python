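"""Mechanistic generator of annotation and aligned reads.

The generator emulates an operonic bacterial genome and the footprint
libraries of a recycling-depletion experiment:

* operons of ~1 + Poisson(mean - 1) genes; CDS lengths log-normal (multiple
  of 3, >= 150 nt); within-operon stop/start overlaps (distance -4) with
  probability ``p_overlap``, otherwise short geometric intergenic gaps;
  TU-terminal 3'-UTRs uniform in [utr3_min, utr3_max].
* per gene an mRNA abundance ``m`` and a ribosome occupancy ``o`` (both
  log-normal, drawn once and shared across all libraries of a run).
* elongating footprints: Poisson per CDS nt at rate ``depth_rpf * m * o``.
* a stop-codon peak of post-termination complexes (post-TCs) at offset 0
  (weight ``w_stop``); upon depletion an extra Poisson load ``f_post(t)``
  of post-TCs per gene, each held at the stop with probability
  ``p_stay(t)`` or displaced geometrically (mean ``diff_geom_mean(t)``)
  into the 3'-UTR, capped at the TU end.
* queued elongating ribosomes behind each stop-resident post-TC, spaced
  one footprint stack (``stack_spacing``) apart, queue length
  min(Poisson(queue_rate * o), available CDS room).
* high-salt lysis: the identical realization with each post-TC-class read
  kept independently with probability ``salt_retention``; elongating-class
  reads (gene body and queues) always survive.
* RNA-seq: uniform Poisson coverage at rate ``depth_rna * m`` over each
  CDS (and the 3'-UTR of TU-terminal genes).

Every footprint yields one read of length ``footprint_len`` ending at its
3' position.  All randomness derives from a single integer seed through
``numpy.random.SeedSequence`` streams keyed by purpose and condition, so a
run is reproducible read-for-read regardless of call order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import Annotation, GeneModel, TranscriptUnit
from .config import GENOTYPES, PREPS, TIME_POINTS, ConfigError, SimConfig
from .io import BED6_COLUMNS

# stream codes for SeedSequence spawning
_S_ANNOT, _S_TRUTH, _S_COUPLING = 10, 0, 3
_S_RNA, _S_REAL, _S_SALT = 20, 30, 40

READ_CLASS_ELONGATING = "elongating"
READ_CLASS_POST = "post"
READ_CLASS_RNA = "rna"

# minimum CDS room (nt) kept free of queued ribosomes near the start codon
QUEUE_START_BUFFER = 60


def _rng(seed: int, *codes: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, codes)]))


def _condition_codes(genotype: str, time_min: int) -> tuple[int, int]:
    if genotype not in GENOTYPES:
        raise ConfigError(f"unknown genotype {genotype!r}")
    if time_min not in TIME_POINTS:
        raise ConfigError(f"unknown time point {time_min!r}")
    return GENOTYPES.index(genotype), TIME_POINTS.index(time_min)


@dataclass
class GeneRealization:
    """Genomic 3'-end positions of one gene's footprints, by class."""

    elong: np.ndarray  # elongating gene-body footprints
    queue: np.ndarray  # queued elongating footprints (salt-resistant)
    post: np.ndarray  # post-TC footprints: stop-resident + displaced


@dataclass
class SimTruth:
    """Ground truth of a simulation run.

    ``genes`` holds per-gene mRNA abundance ``m``, occupancy ``o`` and the
    coupling factor applied to depleted-condition occupancies (1.0 unless
    the coupling knob is on).  ``realizations`` caches the footprint
    realization per (genotype, time) so that standard and high-salt
    libraries of the same sample share it (the salt library is a thinning
    of the standard one).
    """

    genes: pd.DataFrame
    realizations: dict[tuple[str, int], dict[str, GeneRealization]] = field(
        default_factory=dict
    )

    def to_frame(self) -> pd.DataFrame:
        return self.genes.reset_index()


def generate_annotation(config: SimConfig, seed: int | None = None) -> Annotation:
    """Lay out an operonic genome on one chromosome, deterministically."""
    config.validate()
    if config.utr3_max < config.utr3_min:
        raise ConfigError("utr3_max < utr3_min")
    seed = config.seed if seed is None else seed
    rng = _rng(seed, _S_ANNOT)
    chrom = config.chrom_name
    cursor = config.chrom_pad
    genes: list[GeneModel] = []
    tus: list[TranscriptUnit] = []
    placed = 0
    while placed < config.n_genes:
        size = 1 + rng.poisson(max(config.operon_size_mean - 1.0, 0.0))
        size = min(size, config.n_genes - placed)
        strand = "+" if rng.random() < 0.5 else "-"
        lens, gaps = [], []
        for i in range(size):
            raw = rng.lognormal(config.cds_len_log_mean, config.cds_len_log_sd)
            lens.append(3 * max(50, int(round(raw / 3.0))))
            if i:
                if rng.random() < config.p_overlap:
                    gaps.append(-4)
                else:
                    gaps.append(int(rng.geometric(1.0 / config.intergenic_geom_mean)))
        utr = int(rng.integers(config.utr3_min, config.utr3_max + 1))
        leader = 20
        # local coordinates in translation direction
        local = []
        x = leader
        for i, ln in enumerate(lens):
            if i:
                x += gaps[i - 1]
            local.append((x, x + ln))
            x += ln
        tu_len = x + utr
        ids = [f"g{placed + i:04d}" for i in range(size)]
        tu_id = f"tu{len(tus):03d}"
        for gid, (a, b) in zip(ids, local):
            if strand == "+":
                s, e = cursor + a, cursor + b
            else:
                s, e = cursor + tu_len - b, cursor + tu_len - a
            genes.append(GeneModel(gid, chrom, strand, s, e, tu_id))
        tus.append(
            TranscriptUnit(tu_id, chrom, strand, cursor, cursor + tu_len, tuple(ids))
        )
        cursor += tu_len + config.tu_spacer
        placed += size
    chrom_lengths = {chrom: cursor + config.chrom_pad}
    return Annotation(genes, tus, chrom_lengths)


def _draw_truth(annotation: Annotation, config: SimConfig, seed: int) -> SimTruth:
    rng = _rng(seed, _S_TRUTH)
    gids = [g.gene_id for g in annotation.genes]
    m = rng.lognormal(0.0, config.mrna_log_sd, size=len(gids))
    o = rng.lognormal(0.0, config.occ_log_sd, size=len(gids))
    factor = np.ones(len(gids))
    if config.coupling_strength > 0:
        crng = _rng(seed, _S_COUPLING)
        first_of_tu = {tu.gene_ids[0] for tu in annotation.tus}
        for i, g in enumerate(annotation.genes):
            if g.tu_id is not None and g.gene_id not in first_of_tu:
                sign = 1.0 if crng.random() < 0.5 else -1.0
                factor[i] = 2.0 ** (sign * config.coupling_strength)
    genes = pd.DataFrame(
        {"m": m, "o": o, "coupling_factor": factor}, index=pd.Index(gids, name="gene_id")
    )
    return SimTruth(genes)


def _draw_realization(
    annotation: Annotation,
    truth: SimTruth,
    config: SimConfig,
    genotype: str,
    time_min: int,
    seed: int,
) -> dict[str, GeneRealization]:
    gcode, tcode = _condition_codes(genotype, time_min)
    rng = _rng(seed, _S_REAL, gcode, tcode)
    delta = config.stack_spacing
    out: dict[str, GeneRealization] = {}
    for g in annotation.genes:
        row = truth.genes.loc[g.gene_id]
        o_eff = row["o"] * (row["coupling_factor"] if genotype == "KD" else 1.0)
        lam = config.depth_rpf * row["m"] * o_eff
        anchor = g.stop_anchor
        sign = 1 if g.strand == "+" else -1  # translation direction in genome coords

        # elongating gene-body footprints: Poisson per CDS nt
        per_nt = rng.poisson(lam, size=g.cds_len)
        elong = np.repeat(np.arange(g.cds_start, g.cds_end), per_nt)

        # post-TCs at the stop codon (basal peak + retained depletion load)
        n_stop = int(rng.poisson(config.w_stop * lam))
        displaced = np.empty(0, dtype=np.int64)
        if genotype == "KD":
            n_extra = int(rng.poisson(config.f_post[time_min] * lam))
            stay = rng.random(n_extra) < config.p_stay[time_min]
            n_stop += int(stay.sum())
            n_disp = int((~stay).sum())
            if n_disp:
                d = rng.geometric(1.0 / config.diff_geom_mean[time_min], size=n_disp)
                pos = anchor + sign * d
                tu = annotation.tu(g.tu_id) if g.tu_id else None
                if tu is not None:
                    if g.strand == "+":
                        pos = np.minimum(pos, tu.tu_end - 1)
                    else:
                        pos = np.maximum(pos, tu.tu_start)
                else:
                    pos = np.clip(pos, 0, annotation.chrom_lengths[g.chrom] - 1)
                displaced = pos.astype(np.int64)
        post = np.concatenate([np.full(n_stop, anchor, dtype=np.int64), displaced])

        # queues of elongating ribosomes behind each stop-resident post-TC
        kmax = max(0, (g.cds_len - QUEUE_START_BUFFER) // delta)
        queue = np.empty(0, dtype=np.int64)
        if n_stop and kmax:
            ks = np.minimum(rng.poisson(config.queue_rate * o_eff, size=n_stop), kmax)
            jmax = int(ks.max()) if len(ks) else 0
            offs = []
            for j in range(1, jmax + 1):
                cnt = int((ks >= j).sum())
                offs.append(np.full(cnt, anchor - sign * j * delta, dtype=np.int64))
            if offs:
                queue = np.concatenate(offs)
        out[g.gene_id] = GeneRealization(elong, queue, post)
    return out


def _reads_frame(
    chrom: str, positions: np.ndarray, strand: str, length: int, name: str
) -> pd.DataFrame:
    pos = np.asarray(positions, dtype=np.int64)
    if strand == "+":
        start, end = pos - length + 1, pos + 1
    else:
        start, end = pos, pos + length
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": start,
            "end": end,
            "name": name,
            "score": 0,
            "strand": strand,
        }
    )


def simulate_sample(
    annotation: Annotation,
    truth: SimTruth | None,
    config: SimConfig,
    condition: tuple[str, int, str],
    seed: int | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate one library; returns (BED6 reads, truth).

    ``condition`` is (genotype, time_min, prep) with genotype in
    {WT, KD}, time in {5, 15, 60} and prep in {standard, salt, rna}.
    Pass the returned truth back in for further libraries of the same run
    so that abundances (and footprint realizations, for salt thinning)
    are shared.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    genotype, time_min, prep = condition
    if prep not in PREPS:
        raise ConfigError(f"unknown prep {prep!r}")
    gcode, tcode = _condition_codes(genotype, time_min)
    if truth is None:
        truth = _draw_truth(annotation, config, seed)
    L = config.footprint_len
    frames: list[pd.DataFrame] = []

    if prep == "rna":
        rng = _rng(seed, _S_RNA, gcode, tcode)
        for g in annotation.genes:
            rate = config.depth_rna * truth.genes.loc[g.gene_id, "m"]
            per_nt = rng.poisson(rate, size=g.cds_len)
            pos = np.repeat(np.arange(g.cds_start, g.cds_end), per_nt)
            utr = annotation.utr3_interval(g.gene_id)
            if utr is not None:
                per_nt_u = rng.poisson(rate, size=utr[1] - utr[0])
                pos = np.concatenate(
                    [pos, np.repeat(np.arange(utr[0], utr[1]), per_nt_u)]
                )
            if len(pos):
                frames.append(_reads_frame(g.chrom, pos, g.strand, L, READ_CLASS_RNA))
    else:
        key = (genotype, time_min)
        if key not in truth.realizations:
            truth.realizations[key] = _draw_realization(
                annotation, truth, config, genotype, time_min, seed
            )
        real = truth.realizations[key]
        thin_rng = (
            _rng(seed, _S_SALT, gcode, tcode) if prep == "salt" else None
        )
        for g in annotation.genes:
            r = real[g.gene_id]
            post = r.post
            if thin_rng is not None and len(post):
                post = post[thin_rng.random(len(post)) < config.salt_retention]
            elong = np.concatenate([r.elong, r.queue])
            if len(elong):
                frames.append(
                    _reads_frame(g.chrom, elong, g.strand, L, READ_CLASS_ELONGATING)
                )
            if len(post):
                frames.append(_reads_frame(g.chrom, post, g.strand, L, READ_CLASS_POST))

    if frames:
        reads = pd.concat(frames, ignore_index=True)
    else:
        reads = pd.DataFrame(columns=BED6_COLUMNS)
    reads = reads.sort_values(
        ["chrom", "start", "end", "strand", "name"], kind="mergesort"
    ).reset_index(drop=True)
    return reads, truth


def library_id(condition: tuple[str, int, str]) -> str:
    genotype, time_min, prep = condition
    return f"{genotype}_{time_min}_{prep}"


def analytic_expectations(
    annotation: Annotation,
    config: SimConfig,
    truth: SimTruth,
    genotype: str = "KD",
    time_min: int = 5,
    exclude_last: int = 15,
    last_window: int = 100,
) -> tuple[pd.DataFrame, dict]:
    """Closed-form expectations of the per-gene scores under the generator.

    Returns a per-gene frame with expected 3'-UTR and collision scores
    (ratios of expected region densities, first-order in the Poisson
    counts) and a summary dict with the expected high-salt fold change
    (1 / salt_retention) and the expected metagene peak offsets
    {0, -spacing, -2*spacing, ...}.
    """
    from scipy.stats import poisson

    config.validate()
    _condition_codes(genotype, time_min)
    delta = config.stack_spacing
    is_kd = genotype == "KD"
    f_post = config.f_post[time_min] if is_kd else 0.0
    p_stay = config.p_stay[time_min] if is_kd else 0.0
    rows = []
    for g in annotation.genes:
        row = truth.genes.loc[g.gene_id]
        o_eff = row["o"] * (row["coupling_factor"] if is_kd else 1.0)
        lam = config.depth_rpf * row["m"] * o_eff
        s_bar = (config.w_stop + f_post * p_stay) * lam  # stop-resident post-TCs
        kmax = max(0, (g.cds_len - QUEUE_START_BUFFER) // delta)
        mu_k = config.queue_rate * o_eff
        # expected queue reads at offset -j*delta
        q = {
            j: s_bar * float(poisson.sf(j - 1, mu_k)) for j in range(1, kmax + 1)
        }
        eff_cds = g.cds_len - exclude_last
        cds_counts = lam * eff_cds + sum(
            v for j, v in q.items() if j * delta >= exclude_last + 1
        )
        e_cds_density = cds_counts / eff_cds if eff_cds > 0 else np.nan

        utr = annotation.utr3_interval(g.gene_id)
        if utr is not None and e_cds_density and e_cds_density > 0:
            utr_len = utr[1] - utr[0]
            n_utr = f_post * lam * (1.0 - p_stay)
            e_utr3 = (n_utr / utr_len) / e_cds_density
        else:
            e_utr3 = np.nan

        win_eff = last_window - exclude_last
        if g.cds_len > last_window + exclude_last and e_cds_density > 0:
            num = lam * win_eff + sum(
                v
                for j, v in q.items()
                if exclude_last + 1 <= j * delta <= last_window - 1
            )
            e_coll = (num / win_eff) / e_cds_density
        else:
            e_coll = np.nan
        rows.append(
            {"gene_id": g.gene_id, "e_utr3_score": e_utr3, "e_collision_score": e_coll}
        )
    per_gene = pd.DataFrame(rows).set_index("gene_id")
    max_k = max(
        (max(0, (g.cds_len - QUEUE_START_BUFFER) // delta) for g in annotation.genes),
        default=0,
    )
    summary = {
        "salt_fold_change": math.inf
        if config.salt_retention == 0
        else 1.0 / config.salt_retention,
        "peak_offsets": [0] + [-j * delta for j in range(1, min(max_k, 4) + 1)],
    }
    return per_gene, summary
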