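"""End-to-end orchestration: from per-CpG calls to IRDM tiers.

One cell line's analysis is: coverage-filter both replicas, build the
island x replica methylation matrix, call DMRs with the entropy
threshold (SD = 0.03, low 5th percentile) and with the read-count
Fisher test (BH q <= 0.05), and intersect the two call sets.  Across
cell lines the per-line sets feed the overlap-degree and sharing
analyses on the common island universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import hba, methylation, overlap, qdmr
from .types import MethylationMatrix, QdmrThreshold


@dataclass
class CellLineResult:
    cell_line: str
    matrix: MethylationMatrix
    qdmr_table: pd.DataFrame
    hba_table: pd.DataFrame
    irdm: set
    replica_r: float


@dataclass
class IrdmCallSet:
    """Per-cell-line IRDM sets plus the shared-universe bookkeeping."""

    results: dict = field(default_factory=dict)   # cell_line -> CellLineResult

    @property
    def calls_by_line(self) -> dict:
        return {c: r.irdm for c, r in self.results.items()}

    @property
    def universes(self) -> dict:
        return {c: set(r.matrix.complete_universe())
                for c, r in self.results.items()}

    def intersection_universe(self) -> set:
        universes = list(self.universes.values())
        out = universes[0]
        for u in universes[1:]:
            out = out & u
        return out


def analyze_cell_line(calls_rep1: pd.DataFrame, calls_rep2: pd.DataFrame,
                      islands: pd.DataFrame, threshold: QdmrThreshold,
                      cell_line: str = "cell_line",
                      min_coverage: int = methylation.DEFAULT_MIN_COVERAGE,
                      alpha: float = hba.DEFAULT_ALPHA) -> CellLineResult:
    """Two-replica differential calling for one cell line."""
    f1 = methylation.filter_coverage(calls_rep1, min_coverage)
    f2 = methylation.filter_coverage(calls_rep2, min_coverage)
    matrix = methylation.cgi_mean_methylation(
        {"rep1": f1, "rep2": f2}, islands)
    qdmr_table = qdmr.call_dmr(matrix, threshold)
    hba_table = hba.hba_test(f1, f2, islands, alpha=alpha)
    irdm = overlap.call_irdm(
        set(qdmr_table.index[qdmr_table["is_dmr"]]),
        set(hba_table.index[hba_table["is_significant"]]))
    return CellLineResult(
        cell_line=cell_line, matrix=matrix, qdmr_table=qdmr_table,
        hba_table=hba_table, irdm=irdm,
        replica_r=methylation.replica_correlation(matrix))


def analyze_dataset(dataset, sd: float = 0.03, percentile: float = 0.05,
                    n_sim: int = 100_000, seed: int = 0,
                    min_coverage: int = methylation.DEFAULT_MIN_COVERAGE,
                    alpha: float = hba.DEFAULT_ALPHA) -> IrdmCallSet:
    """Run the two-replica analysis on every cell line of a simulation."""
    threshold = qdmr.derive_threshold(2, sd, percentile=percentile,
                                      n_sim=n_sim, seed=seed)
    out = IrdmCallSet()
    for line in dataset.cell_lines:
        out.results[line] = analyze_cell_line(
            dataset.calls[(line, 1)], dataset.calls[(line, 2)],
            dataset.islands, threshold, cell_line=line,
            min_coverage=min_coverage, alpha=alpha)
    return out


def cell_line_mean_matrix(call_set: IrdmCallSet,
                          universe=None) -> MethylationMatrix:
    """Island x cell-line matrix of mean-of-replicas methylation levels.

    Restricted to ``universe`` (default: islands present in every cell
    line) — the input of the cross-cell-line (ICDM) analysis.
    """
    if universe is None:
        universe = call_set.intersection_universe()
    idx = pd.Index(sorted(universe), name="island_id")
    levels, counts = {}, {}
    for line, res in call_set.results.items():
        lv = res.matrix.levels.reindex(idx)
        levels[line] = lv.mean(axis=1)
        counts[line] = res.matrix.n_cpgs.reindex(idx).min(axis=1)
    return MethylationMatrix(levels=pd.DataFrame(levels, index=idx),
                             n_cpgs=pd.DataFrame(counts, index=idx))
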