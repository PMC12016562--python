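"""Configuration objects for every pipeline stage.

Each stage consumes only its own namespaced section; :class:`RunConfig`
bundles them together with the global seed and round-trips through YAML.
Unknown keys are rejected so that typos in a run file fail loudly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "SimConfig",
    "QuantConfig",
    "QCConfig",
    "TrainConfig",
    "EvalConfig",
    "RunConfig",
]


def _from_mapping(cls, data: dict[str, Any]):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(
            f"unknown keys for {cls.__name__}: {sorted(unknown)}; "
            f"allowed: {sorted(allowed)}"
        )
    return cls(**data)


@dataclass
class SimConfig:
    """Conditions for the planted-network simulator.

    The defaults mirror the input structure the predictor expects: a panel of
    593 trans regulators, 42 conserved-sequence motifs around a GGACU core,
    log-normal expression marginals with a heavy right tail, sparse
    regulator-to-site effects acting on log1p expression, and IP libraries
    enriched fourfold over input inside planted peaks.
    """

    n_cells: int = 1000
    n_regulators: int = 593
    n_sites: int = 100
    regulators_per_site: int = 3
    effect_size_sd: float = 0.8
    noise_sd: float = 0.1
    seq_depth: int = 1_000_000
    enrichment_fold: float = 4.0
    seed: int = 0
    # expression marginals: log(expr) ~ Normal(log_mean, log_sd)
    log_mean: float = 1.0
    log_sd: float = 1.0
    dropout_rate: float = 0.0
    n_motifs: int = 42
    motif_consensus: str = "GGACU"
    n_transcripts: int = 50

    def __post_init__(self) -> None:
        for name in ("n_cells", "n_regulators", "n_sites", "regulators_per_site",
                     "seq_depth", "n_motifs", "n_transcripts"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.regulators_per_site > self.n_regulators:
            raise ValueError("regulators_per_site must not exceed n_regulators")
        if self.effect_size_sd <= 0:
            raise ValueError("effect_size_sd must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.enrichment_fold < 1:
            raise ValueError("enrichment_fold must be at least 1")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must lie in [0, 1)")
        for name in ("effect_size_sd", "noise_sd", "log_mean", "log_sd",
                     "enrichment_fold"):
            import math

            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class QuantConfig:
    """Knobs of the winscore quantification.

    A 100-bp window advanced in 50-bp steps makes five sliding windows span
    300 bp, which is the unit the peak-splitting rule is phrased in.  Peaks
    are windows whose pseudo-count-adjusted IP/input RPKM ratio strictly
    exceeds ``winscore_cutoff``.
    """

    window_size: int = 100
    step: int = 50
    winscore_cutoff: float = 2.0
    pseudo_rpkm: float = 1.0
    max_windows_per_peak: int = 5
    gene_median_norm: bool = False
    peak_level_stat: str = "mean"

    def __post_init__(self) -> None:
        if self.step <= 0 or self.window_size <= 0:
            raise ValueError("window_size and step must be positive")
        if self.step > self.window_size:
            raise ValueError("step must not exceed window_size")
        if self.winscore_cutoff <= 0:
            raise ValueError("winscore_cutoff must be positive")
        if self.max_windows_per_peak < 1:
            raise ValueError("max_windows_per_peak must be >= 1")
        if self.peak_level_stat not in ("mean", "max"):
            raise ValueError("peak_level_stat must be 'mean' or 'max'")


@dataclass
class QCConfig:
    """Single-cell QC thresholds (Seurat-style, strict inequalities)."""

    min_features: int = 200
    max_features: int = 4000
    min_counts: int = 200
    max_counts: int = 20000
    max_pct_mito: float = 25.0
    min_cells_per_gene: int = 3
    min_genes_per_cell: int = 200

    def __post_init__(self) -> None:
        if self.min_features >= self.max_features:
            raise ValueError("min_features must be < max_features")
        if self.min_counts >= self.max_counts:
            raise ValueError("min_counts must be < max_counts")
        if self.max_pct_mito <= 0:
            raise ValueError("max_pct_mito must be positive")


@dataclass
class TrainConfig:
    """Model-training protocol: random 70/30 split, 5-fold CV grid search."""

    train_fraction: float = 0.70
    cv_folds: int = 5
    mode: str = "per_site"
    target_transform: str = "identity"
    family: str = "rf"
    grid_search: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.mode not in ("per_site", "global"):
            raise ValueError("mode must be 'per_site' or 'global'")
        if self.target_transform not in ("identity", "log2"):
            raise ValueError("target_transform must be 'identity' or 'log2'")


@dataclass
class EvalConfig:
    """Evaluation protocol: 0.5 tolerance labels, seeded permutation nulls."""

    tolerance: float = 0.5
    n_permutations: int = 1000
    correlation_method: str = "pearson"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.correlation_method not in ("pearson", "spearman"):
            raise ValueError("correlation_method must be 'pearson' or 'spearman'")


@dataclass
class RunConfig:
    """Bundle of all stage configs plus the global seed and output directory."""

    sim: SimConfig = field(default_factory=SimConfig)
    quant: QuantConfig = field(default_factory=QuantConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    seed: int = 0
    outdir: str = "scm6a_run"

    _SECTIONS = {
        "sim": SimConfig,
        "quant": QuantConfig,
        "qc": QCConfig,
        "train": TrainConfig,
        "eval": EvalConfig,
    }

    def with_seed(self, seed: int) -> "RunConfig":
        """Return a copy with the global seed pushed into every stage."""
        cfg = dataclasses.replace(self, seed=seed)
        cfg.sim = dataclasses.replace(cfg.sim, seed=seed)
        cfg.train = dataclasses.replace(cfg.train, seed=seed)
        cfg.eval = dataclasses.replace(cfg.eval, seed=seed)
        return cfg

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {}
        for name, _cls in self._SECTIONS.items():
            out[name] = dataclasses.asdict(getattr(self, name))
        out["seed"] = self.seed
        out["outdir"] = self.outdir
        return out

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        data = dict(data)
        kwargs: dict[str, Any] = {}
        for name, section_cls in cls._SECTIONS.items():
            if name in data:
                kwargs[name] = _from_mapping(section_cls, data.pop(name) or {})
        for scalar in ("seed", "outdir"):
            if scalar in data:
                kwargs[scalar] = data.pop(scalar)
        if data:
            raise ValueError(f"unknown top-level keys in run config: {sorted(data)}")
        return cls(**kwargs)

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError("run config must be a YAML mapping")
        return cls.from_dict(data)
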