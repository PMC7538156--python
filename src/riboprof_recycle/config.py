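"""Configuration for simulation and analysis runs.

Two dataclasses: :class:`SimConfig` holds the generative model of footprint
libraries (depths, post-termination load per depletion time point,
queueing, salt retention); :class:`RunConfig` holds the analysis constants
(clearance window, terminal exclusion, collision window, occupancy
quantiles, fold thresholds) plus I/O paths.  TOML files are parsed with the
standard-library ``tomllib``; unknown keys are rejected so typos fail fast.
"""

from __future__ import annotations

import json
import math
import tomllib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

TIME_POINTS = (5, 15, 60)
GENOTYPES = ("WT", "KD")
PREPS = ("standard", "salt", "rna")


class ConfigError(ValueError):
    """Raised for unparseable, unknown or out-of-range configuration."""


def _as_time_map(value, name: str) -> dict[int, float]:
    if not isinstance(value, dict):
        raise ConfigError(f"{name} must be a table of time point -> value")
    try:
        out = {int(k): float(v) for k, v in value.items()}
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{name}: {exc}") from exc
    if set(out) != set(TIME_POINTS):
        raise ConfigError(
            f"{name} must define exactly the time points {TIME_POINTS}, got {sorted(out)}"
        )
    return out


@dataclass
class SimConfig:
    """Parameters of the synthetic footprint/RNA-seq generator.

    Depths are expected reads per nt per unit abundance.  ``f_post`` is the
    post-termination ribosome load added upon depletion, in nt-equivalents
    of CDS footprint density; ``p_stay`` the probability such a complex is
    still at the stop codon (rather than displaced into the 3'-UTR);
    ``diff_geom_mean`` the mean geometric displacement in nt.  All three are
    per depletion time point (min).  ``salt_retention`` is the probability a
    post-termination footprint survives high-salt lysis.
    """

    n_genes: int = 200
    operon_size_mean: float = 2.5
    cds_len_log_mean: float = math.log(900.0)
    cds_len_log_sd: float = 0.45
    p_overlap: float = 0.3
    intergenic_geom_mean: float = 15.0
    utr3_min: int = 60
    utr3_max: int = 180
    mrna_log_sd: float = 0.8
    occ_log_sd: float = 0.5
    depth_rna: float = 0.5
    depth_rpf: float = 0.5
    footprint_len: int = 28
    stack_spacing: int = 30
    w_stop: float = 15.0
    f_post: dict[int, float] = field(
        default_factory=lambda: {5: 80.0, 15: 160.0, 60: 320.0}
    )
    p_stay: dict[int, float] = field(
        default_factory=lambda: {5: 0.5, 15: 0.35, 60: 0.25}
    )
    diff_geom_mean: dict[int, float] = field(
        default_factory=lambda: {5: 25.0, 15: 50.0, 60: 100.0}
    )
    queue_rate: float = 0.8
    salt_retention: float = 0.4
    coupling_strength: float = 0.0
    tu_spacer: int = 150
    chrom_pad: int = 500
    chrom_name: str = "chrSim"
    seed: int = 0

    def validate(self) -> "SimConfig":
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if self.operon_size_mean < 1:
            raise ConfigError("operon_size_mean must be >= 1")
        if self.cds_len_log_sd < 0:
            raise ConfigError("cds_len_log_sd must be >= 0")
        for name in ("p_overlap", "salt_retention"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for t, v in self.p_stay.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"p_stay[{t}] must be in [0, 1], got {v}")
        for t, v in self.f_post.items():
            if v < 0:
                raise ConfigError(f"f_post[{t}] must be >= 0")
        for t, v in self.diff_geom_mean.items():
            if v < 1:
                raise ConfigError(f"diff_geom_mean[{t}] must be >= 1 nt")
        if self.intergenic_geom_mean < 1:
            raise ConfigError("intergenic_geom_mean must be >= 1 nt")
        if not 0 <= self.utr3_min <= self.utr3_max:
            raise ConfigError("need 0 <= utr3_min <= utr3_max")
        if self.footprint_len < 15:
            raise ConfigError("footprint_len must be >= 15 nt")
        if self.stack_spacing < self.footprint_len:
            raise ConfigError("stack_spacing must be >= footprint_len")
        for name in ("mrna_log_sd", "occ_log_sd", "w_stop", "queue_rate",
                     "coupling_strength"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("depth_rna", "depth_rpf"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.tu_spacer < 0 or self.chrom_pad < 0:
            raise ConfigError("tu_spacer and chrom_pad must be >= 0")
        if self.seed < 0:
            raise ConfigError("seed must be >= 0")
        return self

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown sim config key(s): {', '.join(sorted(unknown))}")
        kwargs = dict(data)
        for name in ("f_post", "p_stay", "diff_geom_mean"):
            if name in kwargs:
                kwargs[name] = _as_time_map(kwargs[name], name)
        try:
            cfg = cls(**kwargs)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        return cfg.validate()


@dataclass
class RunConfig:
    """End-to-end run: inputs (real or simulated) plus analysis constants."""

    simulate: bool = True
    annotation_gff3: str | None = None
    tu_table: str | None = None
    chrom_lengths: str | None = None
    reads: dict[str, str] = field(default_factory=dict)
    sim: SimConfig = field(default_factory=SimConfig)
    # analysis constants
    w_up: int = 120
    w_down: int = 150
    clearance: int = 110
    exclude_last: int = 15
    last_window: int = 100
    top_frac: float = 0.20
    bottom_frac: float = 0.40
    pair_fold: float = 2.0
    rna_max_fold: float = 5.0
    fc_threshold: float = 10.0
    min_rpkm: float = 1.0
    min_cds_reads: int = 32
    peak_search_lo: int = -90
    peak_search_hi: int = -10
    min_prominence: float = 3.0
    metagene_mode: str = "gene-normalized"
    out_dir: str = "out"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> "RunConfig":
        if self.w_up <= 0 or self.w_down <= 0:
            raise ConfigError("w_up and w_down must be > 0")
        if self.clearance < 0:
            raise ConfigError("clearance must be >= 0")
        if self.exclude_last < 0:
            raise ConfigError("exclude_last must be >= 0")
        if self.last_window <= self.exclude_last:
            raise ConfigError("last_window must exceed exclude_last")
        for name in ("top_frac", "bottom_frac"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must be in (0, 1), got {v}")
        if self.top_frac + self.bottom_frac > 1.0:
            raise ConfigError("top_frac + bottom_frac must not exceed 1")
        if self.pair_fold <= 1.0:
            raise ConfigError("pair_fold must be > 1")
        if self.rna_max_fold < 1.0:
            raise ConfigError("rna_max_fold must be >= 1")
        if self.fc_threshold <= 1.0:
            raise ConfigError("fc_threshold must be > 1")
        if self.min_rpkm < 0:
            raise ConfigError("min_rpkm must be >= 0")
        if self.min_cds_reads < 0:
            raise ConfigError("min_cds_reads must be >= 0")
        if not self.peak_search_lo < self.peak_search_hi < 0:
            raise ConfigError("need peak_search_lo < peak_search_hi < 0")
        if self.min_prominence <= 0:
            raise ConfigError("min_prominence must be > 0")
        if self.metagene_mode not in ("gene-normalized", "rpm"):
            raise ConfigError("metagene_mode must be 'gene-normalized' or 'rpm'")
        if self.seed < 0:
            raise ConfigError("seed must be >= 0")
        if not self.simulate:
            for name in ("annotation_gff3", "tu_table"):
                p = getattr(self, name)
                if p is None:
                    raise ConfigError(f"{name} is required when simulate = false")
                if not Path(p).exists():
                    raise ConfigError(f"{name}: no such file {p}")
            for lib, p in self.reads.items():
                if not Path(p).exists():
                    raise ConfigError(f"reads[{lib}]: no such file {p}")
        self.sim.validate()
        return self

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        kwargs = dict(data)
        if "sim" in kwargs:
            kwargs["sim"] = SimConfig.from_dict(kwargs["sim"])
        if "reads" in kwargs and not isinstance(kwargs["reads"], dict):
            raise ConfigError("reads must be a table of library_id -> BED path")
        try:
            cfg = cls(**kwargs)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        return cfg.validate()

    def to_json(self) -> str:
        """Canonical JSON echo of the effective configuration."""
        d = asdict(self)
        for name in ("f_post", "p_stay", "diff_geom_mean"):
            d["sim"][name] = {str(k): v for k, v in sorted(d["sim"][name].items())}
        return json.dumps(d, indent=2, sort_keys=True)


def validate_config(path: str | Path) -> RunConfig:
    """Parse a TOML run configuration; an empty file yields all defaults."""
    path = Path(path)
    try:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    except FileNotFoundError:
        raise ConfigError(f"no such config file: {path}") from None
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    return RunConfig.from_dict(data)
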