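"""Core containers and configuration shared across the pipeline.

Conventions used everywhere in this package:

* genomic coordinates are 0-based half-open,
* methylation levels are fractions in ``[0, 1]``,
* a "sample" is either one replica of a cell line (two-replica analyses)
  or a whole cell line (cross-cell-line analyses).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Mapping

import numpy as np
import pandas as pd
import yaml


class IrdmError(Exception):
    """Base class for pipeline errors."""


class ConfigurationError(IrdmError):
    """Invalid simulation or analysis configuration."""


class ParseError(IrdmError):
    """Malformed input file; message carries the offending line number."""


class ValidationError(IrdmError):
    """Record violates a data invariant (e.g. methylated reads > coverage)."""


class UndefinedResultError(IrdmError):
    """A statistic is requested on input too small/degenerate to define it."""


#: Column layout of a per-CpG methylation call table.
CALL_COLUMNS = ["chrom", "pos", "coverage", "methylated_reads"]

#: Column layout of a CpG-island track table.
ISLAND_COLUMNS = [
    "chrom", "start", "end", "island_id",
    "length", "cpg_count", "gc_fraction", "obs_exp",
]

#: Column layout of a gene-model table.
GENE_COLUMNS = [
    "gene_id", "chrom", "strand", "tx_start", "tx_end",
    "cds_start", "exon_starts", "exon_ends",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic RRBS-like data generator.

    The defaults describe the study conditions the pipeline is calibrated
    for: five cell lines with two replicas each, 2000 CpG islands spread
    over five autosomes and one X chromosome, per-CpG read depth that is
    overdispersed around 30x, intrinsic biological noise with standard
    deviation 0.03 on the methylation fraction, and 10% of islands planted
    as truly differential between replicas with an absolute methylation
    shift of 0.4.  Planted islands are mostly shared across cell lines
    (shared fraction 0.8), biased toward the X chromosome and given a
    small G+C deficit, mirroring the structure the analysis is meant to
    detect.
    """

    n_cell_lines: int = 5
    n_cgis: int = 2000
    chromosome_layout: Mapping[str, int] = field(default_factory=lambda: {
        "chr1": 500, "chr2": 400, "chr3": 350,
        "chr4": 300, "chr5": 250, "chrX": 200,
    })
    #: mean / minimum of the per-island CpG count (truncated Poisson).
    cpg_mean: float = 15.0
    cpg_min: int = 3
    #: negative-binomial read-depth model: mean and dispersion (size) r.
    coverage_mean: float = 30.0
    coverage_dispersion: float = 5.0
    #: SD of the per-CpG, per-replica Normal perturbation of the level.
    biological_sd: float = 0.03
    #: fraction of islands per cell line that are truly differential.
    planted_irdm_fraction: float = 0.10
    #: absolute methylation difference between replicas of planted islands.
    planted_shift: float = 0.4
    #: whether planted islands are drawn from a shared pool, and how often.
    shared_planting: bool = True
    shared_fraction: float = 0.8
    #: sampling-weight multipliers applied per chromosome when choosing
    #: susceptible islands (values > 1 concentrate planting there).
    chromosome_bias: Mapping[str, float] = field(
        default_factory=lambda: {"chrX": 8.0})
    #: additive shifts applied to structural fields of susceptible islands.
    feature_bias: Mapping[str, float] = field(
        default_factory=lambda: {"gc_fraction": -0.02})
    #: number of simulated gene models.
    n_genes: int = 400
    #: multiplicative inflation of replica expression noise for genes whose
    #: regulatory domain touches a planted island (0 = no effect).
    expression_dr_shift: float = 0.5
    #: baseline log-scale SD of replica expression noise.
    expression_sigma: float = 0.2
    #: round-robin assignment of cell lines to these phenotype groups.
    cell_line_groups: tuple = ("cancer", "EBV", "normal")
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chromosome_layout:
            raise ConfigurationError("chromosome_layout must be non-empty")
        if sum(self.chromosome_layout.values()) != self.n_cgis:
            raise ConfigurationError(
                "chromosome_layout counts must sum to n_cgis "
                f"({sum(self.chromosome_layout.values())} != {self.n_cgis})")
        if any(n < 0 for n in self.chromosome_layout.values()):
            raise ConfigurationError("negative CGI count in layout")
        if not 0.0 <= self.planted_irdm_fraction <= 1.0:
            raise ConfigurationError("planted_irdm_fraction must be in [0,1]")
        if not 0.0 < self.planted_shift <= 1.0:
            raise ConfigurationError("planted_shift must be in (0,1]")
        if self.biological_sd < 0:
            raise ConfigurationError("biological_sd must be >= 0")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ConfigurationError("shared_fraction must be in [0,1]")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery checks.

    ``table`` is a long-format frame with one row per (cell line, island):
    columns ``cell_line, island_id, planted, mu, mu_rep1, mu_rep2`` where
    ``mu_rep*`` are the true (pre-noise) replica methylation levels.
    """

    table: pd.DataFrame

    def planted_ids(self, cell_line: str) -> set:
        t = self.table
        sel = (t["cell_line"] == cell_line) & t["planted"]
        return set(t.loc[sel, "island_id"])

    @property
    def cell_lines(self) -> list:
        return list(pd.unique(self.table["cell_line"]))


@dataclass
class MethylationMatrix:
    """Region x sample methylation levels with per-entry CpG support.

    ``levels``: DataFrame indexed by island_id, one column per sample,
    entries in [0,1] or NaN where no qualifying CpG was observed.
    ``n_cpgs``: same shape, number of qualifying CpGs behind each entry.
    """

    levels: pd.DataFrame
    n_cpgs: pd.DataFrame

    @property
    def samples(self) -> list:
        return list(self.levels.columns)

    def complete_universe(self) -> pd.Index:
        """Islands with a non-missing level in every sample."""
        return self.levels.dropna().index

    def __post_init__(self) -> None:
        vals = self.levels.to_numpy(float)
        ok = np.isnan(vals) | ((vals >= 0) & (vals <= 1))
        if not ok.all():
            raise ValidationError("methylation levels must lie in [0,1]")
        support = self.n_cpgs.to_numpy(float)
        nonmiss = ~np.isnan(vals)
        if (support[nonmiss] < 1).any():
            raise ValidationError(
                "non-missing matrix entries need >= 1 supporting CpG")


@dataclass(frozen=True)
class QdmrThreshold:
    """Null-derived cutoff on the adjusted entropy H_Q.

    A region is called differentially methylated when its H_Q falls
    strictly below ``threshold_hq``, the low-tail ``percentile`` of the
    simulated null H_Q distribution at noise level ``sd``.
    """

    n_samples: int
    sd: float
    percentile: float
    threshold_hq: float
    n_sim: int
    seed: int
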