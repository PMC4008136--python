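"""Genomic characterization of differential-island sets.

Covers: chromosome-level bootstrap enrichment, the four-class gene
region scheme (5', intragenic, 3', intergenic) with a chi-square test,
structural-feature comparisons (G+C, length, observed/expected CpG
ratio) by Welch t-test, cross-cell-line differential calling (ICDM) at
the conservative SD = 0.015 setting with Fisher enrichment of IRDM
tiers in the ICDM set, and a Welch one-way analysis of means across
cell-type groups.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.oneway import anova_oneway

from . import qdmr
from .types import MethylationMatrix, UndefinedResultError

log = logging.getLogger("irdm")

FLANK = 3_000
ICDM_SD = 0.015
CLASSES = ("five_prime", "intragenic", "three_prime", "intergenic")


def chromosome_bootstrap(irdm_ids: set, islands: pd.DataFrame,
                         n_boot: int = 10_000, seed: int = 0
                         ) -> pd.DataFrame:
    """Per-chromosome enrichment of a call set against a bootstrap null.

    Each bootstrap draws ``|irdm_ids|`` islands without replacement from
    the universe and records the per-chromosome proportion.  The
    empirical p-value ``(1 + #{sims >= observed}) / (n_boot + 1)`` is
    one-sided for enrichment and never exactly zero.
    """
    chrom_of = islands.set_index("island_id")["chrom"]
    k = len(irdm_ids)
    if k == 0:
        raise UndefinedResultError("empty call set")
    chroms = list(pd.unique(islands["chrom"]))
    universe_counts = islands["chrom"].value_counts().reindex(chroms)
    obs_counts = chrom_of.loc[list(irdm_ids)].value_counts().reindex(
        chroms, fill_value=0)
    rng = np.random.default_rng(seed)
    # joint per-chromosome counts of a without-replacement sample
    sims = rng.multivariate_hypergeometric(
        universe_counts.to_numpy(), k, size=n_boot)
    rows = []
    for j, chrom in enumerate(chroms):
        obs = obs_counts[chrom] / k
        sim_prop = sims[:, j] / k
        p = (1 + int((sim_prop >= obs).sum())) / (n_boot + 1)
        rows.append((chrom, int(obs_counts[chrom]),
                     int(universe_counts[chrom]), obs,
                     float(sim_prop.mean()), p,
                     "enriched" if obs > sim_prop.mean() else "depleted"))
    return pd.DataFrame(rows, columns=[
        "chrom", "observed", "universe", "observed_prop",
        "expected_prop", "p_value", "direction"])


def _gene_zones(gene) -> dict:
    """Genomic intervals of the 5' and 3' zones of one gene model.

    On the + strand the 5' zone runs from 3 kb upstream of the
    translational start through the first intron; the 3' zone covers the
    final intron and final exon.  Minus-strand genes mirror this.
    Single-exon genes have no introns: the 5' zone ends at the exon end.
    """
    starts, ends = gene.exon_starts, gene.exon_ends
    n = len(starts)
    if gene.strand == "+":
        five_end = starts[1] if n > 1 else gene.tx_end  # through intron 1
        five = (gene.cds_start - FLANK, five_end)
        three = (ends[-2] if n > 1 else gene.tx_start, gene.tx_end)
    else:
        five_start = ends[-2] if n > 1 else gene.tx_start
        five = (five_start, gene.cds_start + FLANK)
        three = (gene.tx_start, starts[1] if n > 1 else gene.tx_end)
    return {"five": five, "three": three}


def classify_gene_region(islands: pd.DataFrame, genes: pd.DataFrame,
                         flank: int = FLANK) -> pd.Series:
    """Four-class location of each island, decided by its midpoint.

    Classes: ``five_prime`` (3 kb upstream of the translational start
    through the first intron), ``intragenic`` (internal exons/introns),
    ``three_prime`` (final intron/exon, plus the otherwise-unclassified
    strip within 3 kb of a gene), ``intergenic`` (>= 3 kb from every
    gene).  When several genes disagree the precedence is
    5' > 3' > intragenic.
    """
    rank = {"five_prime": 0, "three_prime": 1, "intragenic": 2}
    mid = ((islands["start"] + islands["end"]) // 2).to_numpy()
    out = pd.Series("intergenic", index=islands["island_id"].to_numpy(),
                    dtype=object)
    for i, isl in enumerate(islands.itertuples()):
        m = mid[i]
        best = None
        for gene in genes[genes["chrom"] == isl.chrom].itertuples():
            if m < gene.tx_start - flank or m >= gene.tx_end + flank:
                continue
            zones = _gene_zones(gene)
            if zones["five"][0] <= m < zones["five"][1]:
                cls = "five_prime"
            elif zones["three"][0] <= m < zones["three"][1]:
                cls = "three_prime"
            elif gene.tx_start <= m < gene.tx_end:
                cls = "intragenic"
            else:
                # inside the 3 kb flank but matching no zone rule
                cls = "three_prime"
            if best is None or rank[cls] < rank[best]:
                best = cls
        if best is not None:
            out.iloc[i] = best
    return out


def gene_region_chisq(classes_subset: pd.Series,
                      classes_all: pd.Series) -> dict:
    """Pearson chi-square of a subset's class counts vs all-island rates."""
    obs = classes_subset.value_counts().reindex(CLASSES, fill_value=0)
    ref = classes_all.value_counts().reindex(CLASSES, fill_value=0)
    props = ref / ref.sum()
    expected = props * obs.sum()
    keep = expected > 0
    if (~keep & (obs > 0)).any():
        raise UndefinedResultError(
            "observed count in a class with zero expected frequency")
    stat, p = stats.chisquare(obs[keep], expected[keep])
    return {"statistic": float(stat), "p_value": float(p),
            "observed": obs, "expected": expected}


def structural_feature_tests(irdm_islands: pd.DataFrame,
                             other_islands: pd.DataFrame,
                             features=("gc_fraction", "length", "obs_exp")
                             ) -> pd.DataFrame:
    """Welch two-sided t-tests on island structural features."""
    if len(irdm_islands) < 2 or len(other_islands) < 2:
        raise UndefinedResultError("each group needs >= 2 islands")
    rows = []
    for feat in features:
        a = irdm_islands[feat].to_numpy(float)
        b = other_islands[feat].to_numpy(float)
        if np.var(a) == 0 and np.var(b) == 0:
            log.warning("feature %s has zero variance in both groups", feat)
            p = 1.0 if a.mean() == b.mean() else 0.0
            t = 0.0 if a.mean() == b.mean() else np.inf
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append((feat, float(a.mean()), float(b.mean()),
                     float(t), float(p)))
    return pd.DataFrame(rows, columns=[
        "feature", "mean_irdm", "mean_other", "t_statistic", "p_value"])


def call_icdm(cell_line_matrix: MethylationMatrix, sd: float = ICDM_SD,
              percentile: float = 0.05, n_sim: int = 100_000,
              seed: int = 0) -> set:
    """Islands differentially methylated *across* cell lines.

    ``cell_line_matrix`` has one column per cell line (each entry the
    mean of the two replica levels).  The same entropy machinery is run
    at the conservative SD = 0.015 threshold setting.
    """
    n = len(cell_line_matrix.samples)
    if n < 2:
        raise UndefinedResultError("ICDM calling needs >= 2 cell lines")
    thr = qdmr.derive_threshold(n, sd, percentile=percentile,
                                n_sim=n_sim, seed=seed)
    res = qdmr.call_dmr(cell_line_matrix, thr)
    return set(res.index[res["is_dmr"]])


def icdm_enrichment(tier_sets: dict[str, set], icdm_set: set,
                    universe) -> pd.DataFrame:
    """Fisher enrichment of each IRDM tier in the ICDM set.

    Tested on the shared universe: 2x2 of (in tier x in ICDM).  A
    degenerate margin (ICDM covering or missing the whole universe)
    yields an undefined odds ratio, reported as NaN with p = 1.
    """
    universe = set(universe)
    icdm = icdm_set & universe
    rows = []
    for name, tier in tier_sets.items():
        t = tier & universe
        a = len(t & icdm)
        b = len(t - icdm)
        c = len(icdm - t)
        d = len(universe - t - icdm)
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            rows.append((name, a, b, c, d, float("nan"), 1.0,
                         len(t & icdm) / len(t) if t else float("nan")))
            continue
        odds, p = stats.fisher_exact([[a, b], [c, d]])
        rows.append((name, a, b, c, d, float(odds), float(p),
                     a / (a + b)))
    return pd.DataFrame(rows, columns=[
        "tier", "tier_icdm", "tier_not_icdm", "rest_icdm", "rest_not_icdm",
        "odds_ratio", "p_value", "tier_icdm_fraction"])


def welch_group_test(counts_by_group: dict[str, list]) -> dict:
    """Welch one-way analysis of means on per-cell-line call counts.

    Groups are cell-type categories (e.g. cancer / EBV / normal), each
    contributing the IRDM counts of its member cell lines.  When every
    observation is identical the statistic is undefined and p is
    reported as 1.
    """
    groups = {g: np.asarray(v, float) for g, v in counts_by_group.items()}
    if len(groups) < 2:
        raise UndefinedResultError("need >= 2 groups")
    for g, v in groups.items():
        if len(v) < 2:
            raise UndefinedResultError(f"group {g!r} has < 2 cell lines")
    allvals = np.concatenate(list(groups.values()))
    if np.ptp(allvals) == 0:
        return {"p_value": 1.0, "statistic": 0.0}
    res = anova_oneway(list(groups.values()), use_var="unequal",
                       welch_correction=True)
    return {"p_value": float(res.pvalue), "statistic": float(res.statistic)}
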