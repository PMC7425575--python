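"""Configuration objects for the simulation and the end-to-end pipeline.

All stage thresholds default to the published analysis values and all
inequalities are applied strictly (coverage > 10, |diff| > 15, q < 0.01,
adjusted p < 0.01, enrichment p < 0.05, kappa > 0.5, score > 0.9).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import Mapping

import yaml


class ConfigError(ValueError):
    """A configuration value is missing, unknown or out of range."""


def _as_group_sizes(value) -> tuple[int, int]:
    if isinstance(value, int):
        return (value, value)
    pair = tuple(int(v) for v in value)
    if len(pair) != 2:
        raise ConfigError("n_samples_per_group must be an int or a pair")
    return pair


@dataclass
class SimulationConfig:
    """Parameters of the synthetic two-group methylome + transcriptome study.

    Defaults emulate the study design this package targets: two sample
    groups of sizes 21 and 32 separated by an HbA1c-like covariate
    (means 8.7% vs 7.8%), RRBS-scale CpG coverage (~30x), planted
    methylation differences of 30 percentage points at 10% of sites, and
    planted 2-fold-log2 expression changes at 10% of genes.

    Attributes
    ----------
    n_samples_per_group : int or (int, int)
        Sizes of group 1 and group 2.
    n_genes, n_cpgs : int
        Number of gene models and CpG sites on the toy genome.
    chrom_sizes : mapping chromosome -> length in bp.
    frac_dm_cpgs : float
        Proportion of CpGs with a planted group difference.
    planted_meth_diff : float
        Planted group-1 minus group-2 methylation shift, percentage points.
    mean_coverage : float
        Mean per-site read coverage; per-sample coverage is
        negative-binomial with dispersion ``coverage_dispersion``.
    beta_binomial_precision : float
        Precision of the per-sample beta-distributed methylation level
        (larger = closer to pure binomial counts).
    frac_de_genes, planted_log2fc, nb_dispersion : float
        Expression side: proportion of DE genes, planted |log2 fold
        change|, and negative-binomial dispersion of gene counts.
    covariate_mean_by_group : mapping group -> HbA1c-like mean (%).
    covariate_sd : float
        Within-group SD of the covariate (%).
    seed : int
        Master seed; a fixed seed yields byte-identical output files.
    """

    n_samples_per_group: tuple[int, int] | int = (21, 32)
    n_genes: int = 200
    n_cpgs: int = 2000
    chrom_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 2_000_000, "chr2": 1_500_000}
    )
    frac_dm_cpgs: float = 0.10
    planted_meth_diff: float = 30.0
    mean_coverage: float = 30.0
    coverage_dispersion: float = 0.3
    beta_binomial_precision: float = 150.0
    frac_de_genes: float = 0.10
    planted_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    covariate_mean_by_group: Mapping[str, float] = field(
        default_factory=lambda: {"group1": 8.7, "group2": 7.8}
    )
    covariate_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.n_samples_per_group = _as_group_sizes(self.n_samples_per_group)
        self.validate()

    @property
    def group_sizes(self) -> tuple[int, int]:
        return _as_group_sizes(self.n_samples_per_group)

    @property
    def n_samples(self) -> int:
        n1, n2 = self.group_sizes
        return n1 + n2

    def validate(self) -> None:
        for name in ("frac_dm_cpgs", "frac_de_genes"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.planted_meth_diff <= 100.0:
            raise ConfigError(
                f"planted_meth_diff must lie in (0, 100], got {self.planted_meth_diff}"
            )
        if self.mean_coverage <= 0:
            raise ConfigError("mean_coverage must be positive")
        if self.coverage_dispersion < 0 or self.nb_dispersion < 0:
            raise ConfigError("dispersions must be non-negative")
        if self.beta_binomial_precision <= 0:
            raise ConfigError("beta_binomial_precision must be positive")
        if self.covariate_sd <= 0:
            raise ConfigError("covariate_sd must be positive")
        if min(self.group_sizes) < 1 or self.n_genes < 1 or self.n_cpgs < 1:
            raise ConfigError("group sizes, n_genes and n_cpgs must be >= 1")
        if not self.chrom_sizes:
            raise ConfigError("chrom_sizes must be non-empty")
        if set(self.covariate_mean_by_group) != {"group1", "group2"}:
            raise ConfigError("covariate_mean_by_group needs keys group1/group2")


@dataclass
class PipelineConfig:
    """Thresholds and knobs for every pipeline stage.

    Defaults are the published values: coverage > 10 reads, site present
    in > threshold coverage in >= 10 samples per group, |methylation
    difference| > 15 points with q < 0.01 for DMCs, BH-adjusted p < 0.01
    for DEGs, enrichment cutoff 0.05 (BH-adjusted for DEG-style runs,
    nominal for DMG-style runs), kappa > 0.5 with >= 5 terms per cluster,
    interaction score > 0.9, promoter window 5000 bp upstream of the TSS,
    CpG shore width 2000 bp, and k = 3 expression clusters.
    """

    min_coverage: int = 10
    min_per_group: int = 10
    meth_diff_threshold: float = 15.0
    q_threshold: float = 0.01
    de_adj_p_threshold: float = 0.01
    enrich_cutoff: float = 0.05
    enrich_mode_deg: str = "adjusted"
    enrich_mode_dmg: str = "nominal"
    kappa_threshold: float = 0.5
    min_cluster_terms: int = 5
    network_score_threshold: float = 0.9
    network_min_subnetwork: int = 3
    promoter_bp: int = 5000
    shore_bp: int = 2000
    k_clusters: int = 3
    excluded_chromosomes: tuple[str, ...] = ("chrX", "chrY")
    seed: int = 0

    def validate(self) -> None:
        for name in ("q_threshold", "de_adj_p_threshold", "enrich_cutoff"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ConfigError(f"{name} must lie in (0, 1], got {v}")
        if not 0.0 < self.meth_diff_threshold < 100.0:
            raise ConfigError("meth_diff_threshold must lie in (0, 100)")
        if not 0.0 <= self.network_score_threshold <= 1.0:
            raise ConfigError("network_score_threshold must lie in [0, 1]")
        if not -1.0 <= self.kappa_threshold <= 1.0:
            raise ConfigError("kappa_threshold must lie in [-1, 1]")
        for name in ("min_coverage", "min_per_group", "min_cluster_terms",
                     "promoter_bp", "shore_bp", "k_clusters",
                     "network_min_subnetwork"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        for name in ("enrich_mode_deg", "enrich_mode_dmg"):
            if getattr(self, name) not in ("adjusted", "nominal"):
                raise ConfigError(f"{name} must be 'adjusted' or 'nominal'")
        if self.k_clusters < 1:
            raise ConfigError("k_clusters must be >= 1")


def validate_config(raw: Mapping | None) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a parsed YAML mapping.

    Unknown keys raise a :class:`ConfigError` listing the valid ones;
    missing keys take the published defaults; ranges are checked.
    """
    raw = dict(raw or {})
    valid = {f.name for f in fields(PipelineConfig)}
    unknown = sorted(set(raw) - valid)
    if unknown:
        raise ConfigError(
            f"unknown config keys {unknown}; valid keys: {sorted(valid)}"
        )
    if "excluded_chromosomes" in raw:
        raw["excluded_chromosomes"] = tuple(raw["excluded_chromosomes"])
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def load_pipeline_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is not None and not isinstance(raw, Mapping):
        raise ConfigError("pipeline config must be a YAML mapping")
    return validate_config(raw)


def load_simulation_config(path) -> SimulationConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, Mapping):
        raise ConfigError("simulation config must be a YAML mapping")
    valid = {f.name for f in fields(SimulationConfig)}
    unknown = sorted(set(raw) - valid)
    if unknown:
        raise ConfigError(
            f"unknown config keys {unknown}; valid keys: {sorted(valid)}"
        )
    return SimulationConfig(**raw)


def config_as_dict(cfg) -> dict:
    d = asdict(cfg)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d
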