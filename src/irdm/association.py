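"""Region-to-gene association and downstream enrichment / expression tests.

Gene regulatory domains follow the basal-plus-extension rule: the basal
domain runs from 5,000 bp upstream to 1,000 bp downstream of the TSS
(strand-aware); the extended domain grows each side up to 1,000,000 bp
but stops at the nearest neighboring basal domain and at chromosome
ends.  A genomic region is associated with every gene whose extended
domain it intersects.

Term enrichment is tested two ways, and a term counts as enriched only
when both pass after BH correction: a binomial test over regions (each
region "hits" a term with probability equal to the genomic fraction
covered by the term's domains) and a hypergeometric test over genes.

The replica-expression analysis scores each gene with the relative
replica difference ``DR = |expr1 - expr2| / (expr1 + expr2)`` and asks,
via a median-split 2x2 Fisher test, whether genes near differential
islands (IRDM-G) have larger DR than the rest (N-IRDM-G).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import UndefinedResultError

log = logging.getLogger("irdm")

BASAL_UPSTREAM = 5_000
BASAL_DOWNSTREAM = 1_000
MAX_EXTENSION = 1_000_000


def tss(genes: pd.DataFrame) -> pd.Series:
    return genes["tx_start"].where(genes["strand"] == "+", genes["tx_end"])


def build_regulatory_domains(genes: pd.DataFrame,
                             chrom_sizes: dict | None = None
                             ) -> pd.DataFrame:
    """Basal + extended regulatory domain per gene.

    Returns columns ``gene_id, chrom, basal_start, basal_end, ext_start,
    ext_end``.  Extended domains never reach into a neighboring gene's
    basal domain and are clipped at 0 and at the chromosome size when
    one is supplied.
    """
    t = tss(genes)
    plus = genes["strand"] == "+"
    basal_start = np.where(plus, t - BASAL_UPSTREAM, t - BASAL_DOWNSTREAM)
    basal_end = np.where(plus, t + BASAL_DOWNSTREAM, t + BASAL_UPSTREAM)
    dom = pd.DataFrame({
        "gene_id": genes["gene_id"], "chrom": genes["chrom"],
        "basal_start": np.maximum(basal_start, 0),
        "basal_end": basal_end,
    })
    ext_start = np.empty(len(dom), dtype=np.int64)
    ext_end = np.empty(len(dom), dtype=np.int64)
    for chrom, grp in dom.groupby("chrom", sort=False):
        order = grp["basal_start"].argsort(kind="stable").to_numpy()
        idx = grp.index.to_numpy()[order]
        bs = dom.loc[idx, "basal_start"].to_numpy()
        be = dom.loc[idx, "basal_end"].to_numpy()
        size = None if chrom_sizes is None else chrom_sizes.get(chrom)
        for j, i in enumerate(idx):
            lo = bs[j] - MAX_EXTENSION
            hi = be[j] + MAX_EXTENSION
            if j > 0:
                lo = max(lo, be[j - 1])
            if j + 1 < len(idx):
                hi = min(hi, bs[j + 1])
            # truncation never shrinks a domain below its own basal part
            ext_start[dom.index.get_loc(i)] = min(max(lo, 0), bs[j])
            ext_end[dom.index.get_loc(i)] = max(
                hi if size is None else min(hi, size), be[j])
    dom["ext_start"] = ext_start
    dom["ext_end"] = ext_end
    return dom


def _overlaps(regions: pd.DataFrame, intervals: pd.DataFrame,
              start_col: str, end_col: str) -> pd.DataFrame:
    """Long frame (island_id, gene_id) of region/interval intersections."""
    hits = []
    for chrom, reg in regions.groupby("chrom", sort=False):
        dom = intervals[intervals["chrom"] == chrom]
        if len(dom) == 0:
            continue
        rs = reg["start"].to_numpy()[:, None]
        re_ = reg["end"].to_numpy()[:, None]
        ds = dom[start_col].to_numpy()[None, :]
        de = dom[end_col].to_numpy()[None, :]
        ov = (ds < re_) & (de > rs)
        ri, gi = np.nonzero(ov)
        hits.append(pd.DataFrame({
            "island_id": reg["island_id"].to_numpy()[ri],
            "gene_id": dom["gene_id"].to_numpy()[gi]}))
    if not hits:
        return pd.DataFrame(columns=["island_id", "gene_id"])
    return pd.concat(hits, ignore_index=True)


def associate_regions(regions: pd.DataFrame, domains: pd.DataFrame,
                      irdm_ids: set | None = None) -> dict:
    """Associate regions with genes via extended-domain intersection.

    ``regions`` needs columns ``chrom, start, end, island_id``.  Returns
    ``pairs`` (region/gene long frame) and, when ``irdm_ids`` is given,
    the disjoint gene sets ``irdm_genes`` / ``non_irdm_genes`` (a gene
    touched by both kinds of region goes to the IRDM side).
    """
    pairs = _overlaps(regions, domains, "ext_start", "ext_end")
    out = {"pairs": pairs}
    if irdm_ids is not None:
        is_irdm = pairs["island_id"].isin(irdm_ids)
        irdm_genes = set(pairs.loc[is_irdm, "gene_id"])
        non_irdm = set(pairs.loc[~is_irdm, "gene_id"]) - irdm_genes
        out["irdm_genes"] = irdm_genes
        out["non_irdm_genes"] = non_irdm
    return out


def _union_length(starts: np.ndarray, ends: np.ndarray) -> int:
    if len(starts) == 0:
        return 0
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    total, cur_s, cur_e = 0, starts[0], ends[0]
    for s, e in zip(starts[1:], ends[1:]):
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    return int(total + cur_e - cur_s)


def term_enrichment(regions: pd.DataFrame, domains: pd.DataFrame,
                    gene_term_map: pd.DataFrame, gene_universe,
                    genome_length: int, alpha: float = 0.05
                    ) -> pd.DataFrame:
    """Binomial-over-regions and hypergeometric-over-genes term tests.

    ``gene_term_map`` is a long frame ``gene_id, term_id``.  For each
    term: the binomial test asks whether more regions than expected fall
    inside the term genes' extended domains, the expectation being the
    fraction of the genome those domains cover; the hypergeometric test
    asks whether the genes associated with the regions are enriched for
    the term within ``gene_universe``.  Both p-value families are BH
    corrected; ``enriched`` requires both q-values <= ``alpha``.
    """
    if len(gene_term_map) == 0:
        raise UndefinedResultError("term map is empty")
    universe = set(gene_universe)
    if not universe:
        raise UndefinedResultError("gene universe is empty")
    n_regions = len(regions)
    assoc = associate_regions(regions, domains)["pairs"]
    assoc_genes = set(assoc["gene_id"]) & universe
    hits_per_region = assoc.groupby("island_id")["gene_id"].agg(set)

    rows = []
    for term, grp in gene_term_map.groupby("term_id"):
        term_genes = set(grp["gene_id"]) & universe
        dom = domains[domains["gene_id"].isin(term_genes)]
        cov = sum(_union_length(g["ext_start"].to_numpy(),
                                g["ext_end"].to_numpy())
                  for _, g in dom.groupby("chrom"))
        p_hit = min(cov / genome_length, 1.0)
        k_regions = int(sum(bool(gs & term_genes)
                            for gs in hits_per_region))
        if p_hit >= 1.0:
            p_binom = 1.0
        else:
            p_binom = stats.binomtest(k_regions, n_regions, p_hit,
                                      alternative="greater").pvalue
        k_genes = len(assoc_genes & term_genes)
        p_hyper = float(stats.hypergeom.sf(
            k_genes - 1, len(universe), len(term_genes), len(assoc_genes)))
        rows.append((term, len(term_genes), k_regions, p_hit,
                     float(p_binom), k_genes, p_hyper))
    out = pd.DataFrame(rows, columns=[
        "term_id", "n_term_genes", "n_hit_regions", "p_hit",
        "p_binomial", "n_hit_genes", "p_hypergeom"])
    for col in ("p_binomial", "p_hypergeom"):
        out["q_" + col[2:]] = multipletests(out[col], method="fdr_bh")[1]
    out["enriched"] = ((out["q_binomial"] <= alpha)
                       & (out["q_hypergeom"] <= alpha))
    return out


def dr_scores(expression: pd.DataFrame) -> pd.DataFrame:
    """Relative replica difference DR per gene; zero-total genes dropped."""
    total = expression["expr1"] + expression["expr2"]
    dropped = int((total == 0).sum())
    if dropped:
        log.info("excluding %d genes with zero expression in both replicas",
                 dropped)
    kept = expression[total > 0].copy()
    kept["DR"] = ((kept["expr1"] - kept["expr2"]).abs()
                  / (kept["expr1"] + kept["expr2"]))
    return kept


def dr_fisher_test(expression: pd.DataFrame, irdm_gene_set: set) -> dict:
    """Median-split Fisher test of DR between IRDM-G and N-IRDM-G.

    The two DR distributions are merged to find the overall median; each
    group is split into values > median vs <= median, and the resulting
    2x2 table tested with the two-sided Fisher exact test.
    """
    scored = dr_scores(expression)
    in_irdm = scored["gene_id"].isin(irdm_gene_set)
    if in_irdm.all() or not in_irdm.any():
        raise UndefinedResultError("both gene groups must be non-empty")
    median = scored["DR"].median()
    above = scored["DR"] > median
    table = np.array([
        [int((in_irdm & above).sum()), int((in_irdm & ~above).sum())],
        [int((~in_irdm & above).sum()), int((~in_irdm & ~above).sum())],
    ])
    p = float(stats.fisher_exact(table)[1])
    return {"table": table, "p_value": p, "median_dr": float(median),
            "dr": scored.set_index("gene_id")["DR"],
            "n_irdm_g": int(in_irdm.sum()),
            "n_non_irdm_g": int((~in_irdm).sum())}
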