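"""Per-island methylation summaries from coverage-filtered CpG calls.

The level of an island in one sample is the *unweighted* mean over its
qualifying CpGs of ``methylated_reads / coverage`` (mean of per-CpG
fractions, not the pooled read fraction — the read-weighted view is what
the HBA count test covers instead).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from scipy import stats

from .types import MethylationMatrix, UndefinedResultError

DEFAULT_MIN_COVERAGE = 10


def filter_coverage(calls: pd.DataFrame,
                    min_coverage: int = DEFAULT_MIN_COVERAGE) -> pd.DataFrame:
    """Keep only CpGs with read coverage >= ``min_coverage``."""
    return calls[calls["coverage"] >= min_coverage].reset_index(drop=True)


def assign_to_islands(calls: pd.DataFrame,
                      islands: pd.DataFrame) -> pd.Series:
    """Island id containing each CpG (NaN when outside every island).

    Islands are non-overlapping, sorted, 0-based half-open; a CpG at
    position ``end - 1`` is inside, at ``end`` it is not.
    """
    out = pd.Series(pd.NA, index=calls.index, dtype="object")
    for chrom, isl in islands.groupby("chrom", sort=False):
        sel = calls["chrom"] == chrom
        if not sel.any():
            continue
        pos = calls.loc[sel, "pos"].to_numpy()
        starts = isl["start"].to_numpy()
        ends = isl["end"].to_numpy()
        ids = isl["island_id"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        assigned = np.where(ok, ids[np.clip(idx, 0, None)], None)
        out.loc[sel] = assigned
    return out


def cgi_mean_methylation(calls_by_sample: dict[str, pd.DataFrame],
                         islands: pd.DataFrame,
                         require_all_samples: bool = True
                         ) -> MethylationMatrix:
    """Region x sample matrix of mean CpG methylation fractions.

    ``calls_by_sample`` maps a sample id to its (already coverage
    filtered) call table.  Entries with zero qualifying CpGs are missing;
    when ``require_all_samples`` is set, islands missing in any sample
    are dropped from the matrix entirely, so only islands with data in
    every replica enter the analysis.
    """
    if len(islands) == 0:
        raise UndefinedResultError("island list is empty")
    level_cols, count_cols = {}, {}
    index = pd.Index(islands["island_id"], name="island_id")
    for sample, calls in calls_by_sample.items():
        calls = calls.copy()
        calls["island_id"] = assign_to_islands(calls, islands)
        inside = calls.dropna(subset=["island_id"])
        frac = inside["methylated_reads"] / inside["coverage"]
        grouped = frac.groupby(inside["island_id"])
        level_cols[sample] = grouped.mean().reindex(index)
        count_cols[sample] = grouped.size().reindex(index).fillna(0)
    levels = pd.DataFrame(level_cols, index=index)
    counts = pd.DataFrame(count_cols, index=index)
    counts = counts.where(levels.notna())
    if require_all_samples:
        keep = levels.notna().all(axis=1)
        levels, counts = levels[keep], counts[keep]
    return MethylationMatrix(levels=levels, n_cpgs=counts)


def replica_correlation(matrix: MethylationMatrix) -> float:
    """Pearson correlation of the two replica columns across islands."""
    if len(matrix.samples) != 2:
        raise UndefinedResultError("replica correlation needs 2 samples")
    both = matrix.levels.dropna()
    if len(both) < 3:
        raise UndefinedResultError(
            f"need >= 3 islands with data in both replicas, got {len(both)}")
    a, b = both.iloc[:, 0], both.iloc[:, 1]
    return float(stats.pearsonr(a, b).statistic)
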