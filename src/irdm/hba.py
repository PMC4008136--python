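"""Hypergeometric-based approach (HBA): read-count testing per island.

Per-CpG methylation estimates from RRBS are sensitive to read coverage,
and the island mean to how many CpGs were assayed.  HBA sidesteps both
by pooling reads: for each island and replica the methylated and
unmethylated read counts of all qualifying CpGs (coverage >= 10) are
summed, the resulting 2x2 table (replica x methylated/unmethylated) is
tested with Fisher's exact test, and Benjamini-Hochberg FDR is applied
across the islands of the comparison.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .methylation import assign_to_islands
from .types import UndefinedResultError

log = logging.getLogger("irdm")

DEFAULT_ALPHA = 0.05


def aggregate_counts(calls_rep1: pd.DataFrame, calls_rep2: pd.DataFrame,
                     islands: pd.DataFrame) -> pd.DataFrame:
    """Per-island pooled read counts for both replicas.

    Input calls must already be coverage-filtered.  Islands with no
    qualifying CpG in either replica are excluded.  Returns a frame
    indexed by island id with columns ``meth_rep1, unmeth_rep1,
    meth_rep2, unmeth_rep2``.
    """
    cols = {}
    for rep, calls in (("rep1", calls_rep1), ("rep2", calls_rep2)):
        calls = calls.copy()
        calls["island_id"] = assign_to_islands(calls, islands)
        inside = calls.dropna(subset=["island_id"])
        g = inside.groupby("island_id")
        meth = g["methylated_reads"].sum()
        total = g["coverage"].sum()
        cols[f"meth_{rep}"] = meth
        cols[f"unmeth_{rep}"] = total - meth
    table = pd.DataFrame(cols).dropna().astype(int)
    return table[["meth_rep1", "unmeth_rep1", "meth_rep2", "unmeth_rep2"]]


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Two-sidedness follows the point-probability rule: the p-value sums
    the hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed the observed table's.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if t[0].sum() == 0 or t[1].sum() == 0:
        raise UndefinedResultError("zero row sum: table untestable")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def hba_filter(counts: pd.DataFrame,
               alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Fisher-test every island's pooled table and BH-correct.

    ``counts`` is the output of :func:`aggregate_counts`.  Adds columns
    ``p_value, q_value, is_significant`` (``q_value <= alpha``).  Islands
    whose table has a zero row sum are dropped with a warning.
    """
    if len(counts) == 0:
        raise UndefinedResultError("no testable islands")
    rows_ok = ((counts["meth_rep1"] + counts["unmeth_rep1"] > 0)
               & (counts["meth_rep2"] + counts["unmeth_rep2"] > 0))
    if not rows_ok.all():
        log.warning("dropping %d islands with zero reads in one replica",
                    (~rows_ok).sum())
        counts = counts[rows_ok]
    pvals = np.empty(len(counts))
    arr = counts.to_numpy()
    for i, (m1, u1, m2, u2) in enumerate(arr):
        pvals[i] = stats.fisher_exact([[m1, u1], [m2, u2]])[1]
    reject, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    out = counts.copy()
    out["p_value"] = pvals
    out["q_value"] = qvals
    out["is_significant"] = qvals <= alpha
    return out


def hba_test(calls_rep1: pd.DataFrame, calls_rep2: pd.DataFrame,
             islands: pd.DataFrame,
             alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Aggregate + test + FDR in one call (calls already filtered)."""
    return hba_filter(aggregate_counts(calls_rep1, calls_rep2, islands),
                      alpha=alpha)
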