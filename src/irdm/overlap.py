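"""Cross-cell-line sharing of inter-replica differential islands.

An island is an IRDM-CGI in a cell line when *both* the entropy (QDMR)
and the read-count (HBA) tests call it differential between the two
replicas.  The "overlap degree" of an island is the number of cell lines
calling it; the sharing analysis compares the observed degree
distribution against a Monte Carlo null in which each cell line's calls
are reassigned uniformly at random over the common island universe,
keeping the per-line call count fixed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .types import UndefinedResultError


def call_irdm(qdmr_positive: set, hba_significant: set) -> set:
    """Islands called differential by both methods (set intersection)."""
    return set(qdmr_positive) & set(hba_significant)


def overlap_degrees(calls_by_line: dict[str, set]) -> pd.Series:
    """Per-island count of cell lines calling it IRDM.

    Only islands called at least once appear (minimum degree 1).
    """
    if len(calls_by_line) < 2:
        raise UndefinedResultError("overlap degrees need >= 2 cell lines")
    counts: dict = {}
    for ids in calls_by_line.values():
        for i in ids:
            counts[i] = counts.get(i, 0) + 1
    return pd.Series(counts, dtype=int).sort_index()


def degree_histogram(degrees: pd.Series, n_cell_lines: int) -> pd.Series:
    """Number of islands at each overlap degree 1..n_cell_lines."""
    return degrees.value_counts().reindex(
        range(1, n_cell_lines + 1), fill_value=0).sort_index()


def monte_carlo_overlap_null(calls_by_line: dict[str, set],
                             universe, n_sim: int = 100,
                             seed: int = 0) -> dict:
    """Monte Carlo null for the degree distribution, plus sharing test.

    Each simulation reassigns, per cell line, the same number of IRDM
    labels uniformly at random (without replacement) over ``universe``
    — the islands with methylation data in every cell line.  The
    shared-vs-singleton Fisher test compares observed counts of islands
    with degree 1 versus degree >= 2 against the counts summed over all
    simulations.

    Returns a dict with ``observed_hist``, ``null_hists`` (n_sim x
    degrees DataFrame), ``fisher_table`` and ``fisher_p``.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    universe = list(universe)
    u = len(universe)
    lines = sorted(calls_by_line)
    k = {c: len(set(calls_by_line[c]) & set(universe)) for c in lines}
    if any(k[c] > u for c in lines):
        raise UndefinedResultError("call set larger than universe")
    n_lines = len(lines)
    observed = {c: set(calls_by_line[c]) & set(universe) for c in lines}
    obs_deg = overlap_degrees(observed)
    obs_hist = degree_histogram(obs_deg, n_lines)

    rng = np.random.default_rng(seed)
    null = np.zeros((n_sim, n_lines), dtype=int)  # histogram per sim
    for s in range(n_sim):
        deg = np.zeros(u, dtype=np.int64)
        for c in lines:
            picked = rng.choice(u, size=k[c], replace=False)
            deg[picked] += 1
        binc = np.bincount(deg, minlength=n_lines + 1)
        null[s] = binc[1:n_lines + 1]
    null_hists = pd.DataFrame(null, columns=range(1, n_lines + 1))

    obs_single = int(obs_hist.get(1, 0))
    obs_shared = int(obs_hist[obs_hist.index >= 2].sum())
    sim_single = int(null_hists[1].sum())
    sim_shared = int(null_hists.loc[:, 2:].to_numpy().sum())
    table = np.array([[obs_single, obs_shared], [sim_single, sim_shared]])
    if table.sum(axis=1).min() == 0:
        fisher_p = float("nan")
    else:
        fisher_p = float(stats.fisher_exact(table)[1])
    return {"observed_hist": obs_hist, "null_hists": null_hists,
            "fisher_table": table, "fisher_p": fisher_p}


def define_tiers(degrees: pd.Series, islands: pd.DataFrame,
                 percentile: float = 0.05,
                 x_chroms: tuple = ("chrX", "X")) -> dict:
    """Common (degree >= 2) and most-common tiers of IRDM islands.

    The most-common cutoff is the smallest integer degree ``d`` such
    that the fraction of *autosomal common* degrees ``>= d`` is at most
    ``percentile`` (the top 5% of the autosomal common-degree
    distribution); when no such degree exists the tier is empty.
    """
    common = degrees[degrees >= 2]
    chrom = islands.set_index("island_id")["chrom"]
    autosomal = common[~chrom.reindex(common.index).isin(x_chroms)]
    cutoff = None
    if len(autosomal) > 0:
        vals = autosomal.to_numpy()
        for d in range(2, int(vals.max()) + 1):
            if (vals >= d).mean() <= percentile:
                cutoff = d
                break
    if cutoff is None:
        most_common = set()
    else:
        most_common = set(common[common >= cutoff].index)
    return {"common": set(common.index), "most_common": most_common,
            "most_common_cutoff": cutoff}
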