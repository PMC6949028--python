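"""Run configuration: the single source of every numeric threshold.

No operation in the pipeline hard-codes a cutoff; they all read from a
:class:`RunConfig`, so a run is fully described by (seed, config).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X", "Y", "MT")
AUTOSOMES = tuple(str(i) for i in range(1, 23))
COMPARTMENTS = ("BP", "PV", "CAM")
GROUPS = ("TNL", "TIL", "PTL")


class ConfigError(ValueError):
    """A configuration field failed validation."""


@dataclass
class RunConfig:
    """Pipeline-wide thresholds and scales.

    Attributes
    ----------
    min_genes_per_cell : cells with fewer detected (count>0) genes are dropped.
    min_cells_per_gene : genes detected in fewer retained cells are dropped.
    max_mito_fraction : cells with mitochondrial count fraction above this are
        dropped.
    scale_factor : per-cell library-size target for log-normalization.
    hvg_mean_low, hvg_mean_high, hvg_dispersion_z, hvg_n_bins : variable-gene
        selection window on the (mean, binned z-scored log variance/mean
        dispersion) plane.
    signature_size : maximum genes per cell-type signature.
    signature_q_threshold : marker q-value gate for signature membership.
    min_cells_per_pseudobulk : the 100-cell rule for pseudobulk units.
    de_q_threshold, de_fc_threshold : differential-expression call rule
        (q below threshold AND fold change above threshold).
    shared_q_threshold : stricter q used when classifying effects shared
        between term and preterm labor.
    projection_q_threshold : FDR level for blood-projection tests.
    min_signature_genes_bulk : minimum measured member genes for a valid
        bulk signature score.
    origin_margin : half-width (log10 units) of the indeterminate band
        around the fetal/maternal split.
    """

    seed: int = 0
    min_genes_per_cell: int = 200
    min_cells_per_gene: int = 10
    max_mito_fraction: float = 0.10
    scale_factor: float = 10_000.0
    hvg_mean_low: float = 0.0125
    hvg_mean_high: float = 3.0
    hvg_dispersion_z: float = 0.5
    hvg_n_bins: int = 20
    signature_size: int = 20
    signature_q_threshold: float = 0.05
    marker_min_pct: float = 0.25
    marker_min_logfc: float = 0.25
    min_cells_per_pseudobulk: int = 100
    de_q_threshold: float = 0.1
    de_fc_threshold: float = 2.0
    shared_q_threshold: float = 0.01
    projection_q_threshold: float = 0.1
    min_signature_genes_bulk: int = 3
    origin_margin: float = 0.5
    origin_epsilon: float = 1e-6

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in (
            "min_genes_per_cell",
            "min_cells_per_gene",
            "scale_factor",
            "signature_size",
            "min_cells_per_pseudobulk",
            "de_q_threshold",
            "de_fc_threshold",
            "shared_q_threshold",
            "projection_q_threshold",
            "hvg_n_bins",
            "min_signature_genes_bulk",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive, got {getattr(self, name)}")
        for name in ("max_mito_fraction", "de_q_threshold", "shared_q_threshold",
                     "projection_q_threshold", "signature_q_threshold"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigError(f"{name} must lie in (0, 1), got {v}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ConfigError(f"unknown config field(s): {sorted(bad)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
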