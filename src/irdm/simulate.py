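"""Synthetic RRBS-like inputs with planted differential structure.

The generator emulates the inputs of the inter-replica analysis: a
CpG-island track with structural fields, per-CpG read counts for two
replicas of each simulated cell line, gene models, and two-replica
expression tables.  Per island a true methylation level ``mu`` is drawn
from a bimodal mixture (mostly-unmethylated around 0.05, mostly
methylated around 0.9 — the marginal shape real CpG islands show).
Each CpG of each replica observes ``clip(mu + Normal(0, biological_sd),
0, 1)`` as its methylation probability and draws methylated reads
binomially at a negative-binomially distributed read depth.

A configurable fraction of islands is planted as truly differential
between the two replicas (their replica levels differ by
``planted_shift``).  Planted islands are preferentially drawn from a
pool shared across cell lines, can be concentrated on chosen
chromosomes, and can carry shifted structural features, so every
downstream characterization step has signal to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as irdm_io
from .association import build_regulatory_domains, _overlaps
from .types import ConfigurationError, GroundTruth, SimulationConfig

# island geometry: CpG spacing range (bp) and inter-island gap range
_SPACING = (20, 60)
_GAP = (2_000, 20_000)
_CHROM_MARGIN = 50_000


def _rng(config: SimulationConfig, rng=None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(config.seed)


def generate_cgi_track(config: SimulationConfig,
                       rng: np.random.Generator | None = None
                       ) -> pd.DataFrame:
    """Simulated CpG-island track (sorted, non-overlapping, half-open).

    Besides the on-disk columns the frame carries ``base_mu`` (the true
    shared methylation level) and ``susceptible`` (whether the island
    belongs to the planted pool of any cell line); the per-cell-line
    planting plan is stored in ``df.attrs["planting"]``.  Structural
    feature biases from the config are applied to susceptible islands.
    """
    rng = _rng(config, rng)
    rows = []
    i = 0
    for chrom, n in config.chromosome_layout.items():
        pos = 0
        for _ in range(n):
            n_cpg = max(config.cpg_min, int(rng.poisson(config.cpg_mean)))
            spacing = int(rng.integers(*_SPACING))
            length = n_cpg * spacing
            pos += int(rng.integers(*_GAP))
            start, end = pos, pos + length
            pos = end
            gc = float(np.clip(rng.normal(0.70, 0.05), 0.3, 0.95))
            oe = float(np.clip(rng.normal(0.84, 0.08), 0.4, 1.3))
            rows.append((chrom, start, end, f"CGI_{i:05d}",
                         length, n_cpg, gc, oe))
            i += 1
    df = pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "island_id",
        "length", "cpg_count", "gc_fraction", "obs_exp"])
    # bimodal true methylation level
    high = rng.random(len(df)) < 0.5
    mu = np.where(high, rng.beta(18, 2, len(df)), rng.beta(1, 19, len(df)))
    df["base_mu"] = mu

    planting = _plan_planting(config, df, rng)
    susceptible = set().union(*planting.values()) if planting else set()
    df["susceptible"] = df["island_id"].isin(susceptible)
    for feat, shift in (config.feature_bias or {}).items():
        if feat not in ("gc_fraction", "length", "obs_exp", "cpg_count"):
            raise ConfigurationError(f"cannot bias unknown feature {feat!r}")
        vals = df.loc[df["susceptible"], feat] + shift
        if feat == "gc_fraction":
            vals = vals.clip(0.0, 1.0)
        df.loc[df["susceptible"], feat] = vals
    df.attrs["planting"] = planting
    return df


def _plan_planting(config: SimulationConfig, islands: pd.DataFrame,
                   rng: np.random.Generator) -> dict[str, frozenset]:
    """Choose each cell line's planted island set.

    A global pool of susceptible islands is sampled first (weighted by
    ``chromosome_bias``); each cell line then takes a ``shared_fraction``
    of its planted quota from the pool and the rest privately.
    """
    n_planted = round(config.planted_irdm_fraction * config.n_cgis)
    lines = cell_line_names(config)
    if n_planted == 0:
        return {c: frozenset() for c in lines}
    ids = islands["island_id"].to_numpy()
    w = np.array([
        (config.chromosome_bias or {}).get(c, 1.0)
        for c in islands["chrom"]], dtype=float)
    pool = rng.choice(ids, size=n_planted, replace=False, p=w / w.sum())
    pool_set = set(pool)
    others = np.array(sorted(set(ids) - pool_set))
    n_shared = (round(config.shared_fraction * n_planted)
                if config.shared_planting else 0)
    # private picks are capped by the islands left outside the pool
    n_private = min(n_planted - n_shared, len(others))
    n_shared = n_planted - n_private
    out = {}
    w_others = np.array([
        (config.chromosome_bias or {}).get(c, 1.0)
        for c in islands.set_index("island_id").loc[others, "chrom"]],
        dtype=float)
    for line in lines:
        shared = rng.choice(pool, size=n_shared, replace=False)
        if n_private:
            private = rng.choice(others, size=n_private, replace=False,
                                 p=w_others / w_others.sum())
        else:
            private = []
        out[line] = frozenset(shared) | frozenset(private)
    return out


def cell_line_names(config: SimulationConfig) -> list[str]:
    return [f"cl{i + 1:02d}" for i in range(config.n_cell_lines)]


def cell_line_groups(config: SimulationConfig) -> dict[str, str]:
    groups = config.cell_line_groups
    return {c: groups[i % len(groups)]
            for i, c in enumerate(cell_line_names(config))}


def cpg_positions(island) -> np.ndarray:
    """CpG cytosine positions of an island (regular grid by design)."""
    spacing = island.length // island.cpg_count
    return island.start + spacing * np.arange(island.cpg_count)


def chromosome_sizes(islands: pd.DataFrame) -> dict[str, int]:
    return {c: int(g["end"].max() + _CHROM_MARGIN)
            for c, g in islands.groupby("chrom", sort=False)}


def generate_replica_reads(track: pd.DataFrame, config: SimulationConfig,
                           cell_line: str,
                           rng: np.random.Generator | None = None
                           ) -> tuple[dict[int, pd.DataFrame], pd.DataFrame]:
    """Per-CpG read counts for both replicas of one cell line.

    Returns ``({1: calls, 2: calls}, truth)`` where ``truth`` has one
    row per island: ``cell_line, island_id, planted, mu, mu_rep1,
    mu_rep2``.  Planted islands get replica levels that differ by
    exactly ``planted_shift`` (which replica is hotter is random); all
    others use the island's shared base level in both replicas.
    """
    rng = _rng(config, rng)
    planted = set(track.attrs.get("planting", {}).get(cell_line, ()))
    n = len(track)
    is_planted = track["island_id"].isin(planted).to_numpy()
    mu = track["base_mu"].to_numpy(float)
    mu1, mu2 = mu.copy(), mu.copy()
    if is_planted.any():
        k = int(is_planted.sum())
        lo = rng.uniform(0.02, 1.0 - config.planted_shift - 0.02, size=k)
        hot_is_rep2 = rng.random(k) < 0.5
        mu1[is_planted] = np.where(hot_is_rep2, lo, lo + config.planted_shift)
        mu2[is_planted] = np.where(hot_is_rep2, lo + config.planted_shift, lo)

    ncpg = track["cpg_count"].to_numpy()
    pos = np.concatenate([cpg_positions(isl) for isl in track.itertuples()])
    chroms = np.repeat(track["chrom"].to_numpy(), ncpg)
    p_nb = config.coverage_dispersion / (config.coverage_dispersion
                                         + config.coverage_mean)
    calls = {}
    for rep, mu_rep in ((1, mu1), (2, mu2)):
        level = np.clip(
            np.repeat(mu_rep, ncpg)
            + rng.normal(0.0, config.biological_sd, size=int(ncpg.sum())),
            0.0, 1.0)
        cov = rng.negative_binomial(config.coverage_dispersion, p_nb,
                                    size=level.size)
        meth = rng.binomial(cov, level)
        calls[rep] = pd.DataFrame({
            "chrom": chroms, "pos": pos,
            "coverage": cov, "methylated_reads": meth})
    truth = pd.DataFrame({
        "cell_line": cell_line, "island_id": track["island_id"],
        "planted": is_planted, "mu": mu, "mu_rep1": mu1, "mu_rep2": mu2})
    return calls, truth


def generate_gene_models(config: SimulationConfig,
                         chrom_sizes: dict[str, int],
                         rng: np.random.Generator | None = None
                         ) -> pd.DataFrame:
    """Simulated multi-exon gene models, non-overlapping per chromosome."""
    rng = _rng(config, rng)
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    n_per = np.maximum(
        np.round(config.n_genes * sizes / sizes.sum()).astype(int), 0)
    rows = []
    gi = 0
    for chrom, n in zip(chroms, n_per):
        cursor = int(rng.integers(0, 5_000))
        for _ in range(n):
            n_ex = int(rng.integers(1, 7))
            ex_lens = rng.integers(100, 500, size=n_ex)
            in_lens = rng.integers(200, 2_000, size=max(n_ex - 1, 0))
            tx_len = int(ex_lens.sum() + in_lens.sum())
            cursor += int(rng.integers(1_000, 30_000))
            if cursor + tx_len >= chrom_sizes[chrom]:
                break
            tx_start = cursor
            starts, ends, p = [], [], tx_start
            for j in range(n_ex):
                starts.append(p)
                p += int(ex_lens[j])
                ends.append(p)
                if j < n_ex - 1:
                    p += int(in_lens[j])
            tx_end = ends[-1]
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                cds_start = starts[0] + int(rng.integers(0, ex_lens[0]))
            else:
                cds_start = ends[-1] - int(rng.integers(0, ex_lens[-1]))
            rows.append((f"gene_{gi:04d}", chrom, strand, tx_start, tx_end,
                         cds_start, tuple(starts), tuple(ends)))
            cursor = tx_end
            gi += 1
    return pd.DataFrame(rows, columns=[
        "gene_id", "chrom", "strand", "tx_start", "tx_end",
        "cds_start", "exon_starts", "exon_ends"])


def generate_expression(config: SimulationConfig, truth: pd.DataFrame,
                        genes: pd.DataFrame, islands: pd.DataFrame,
                        chrom_sizes: dict[str, int],
                        rng: np.random.Generator | None = None
                        ) -> pd.DataFrame:
    """Two-replica expression for one cell line's ground truth.

    Replica values are log-normal around a per-gene baseline; genes
    whose regulatory domain intersects a planted island get their
    replica noise inflated by ``1 + expression_dr_shift``.
    """
    rng = _rng(config, rng)
    if len(genes) == 0:
        return pd.DataFrame(columns=["gene_id", "expr1", "expr2"])
    planted_ids = set(truth.loc[truth["planted"], "island_id"])
    domains = build_regulatory_domains(genes, chrom_sizes)
    planted_regions = islands[islands["island_id"].isin(planted_ids)]
    pairs = _overlaps(planted_regions, domains, "ext_start", "ext_end")
    shifted = genes["gene_id"].isin(set(pairs["gene_id"])).to_numpy()
    base = rng.normal(3.0, 1.0, size=len(genes))
    sigma = config.expression_sigma * np.where(
        shifted, 1.0 + config.expression_dr_shift, 1.0)
    e1 = np.exp(base + rng.normal(0.0, sigma))
    e2 = np.exp(base + rng.normal(0.0, sigma))
    return pd.DataFrame({"gene_id": genes["gene_id"],
                         "expr1": e1, "expr2": e2})


@dataclass
class SimulatedDataset:
    """Everything one simulation run produced, in memory."""

    config: SimulationConfig
    islands: pd.DataFrame
    calls: dict = field(default_factory=dict)       # (cell_line, rep) -> df
    truth: GroundTruth | None = None
    genes: pd.DataFrame | None = None
    expression: dict = field(default_factory=dict)  # cell_line -> df
    chrom_sizes: dict = field(default_factory=dict)
    groups: dict = field(default_factory=dict)      # cell_line -> phenotype

    @property
    def cell_lines(self) -> list[str]:
        return cell_line_names(self.config)


def simulate_dataset(config: SimulationConfig,
                     seed: int | None = None) -> SimulatedDataset:
    """Run every generator with one seeded stream; fully deterministic."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    islands = generate_cgi_track(config, rng)
    sizes = chromosome_sizes(islands)
    genes = generate_gene_models(config, sizes, rng)
    calls, truth_parts, expression = {}, [], {}
    for line in cell_line_names(config):
        reps, truth = generate_replica_reads(islands, config, line, rng)
        calls[(line, 1)], calls[(line, 2)] = reps[1], reps[2]
        truth_parts.append(truth)
        expression[line] = generate_expression(
            config, truth, genes, islands, sizes, rng)
    return SimulatedDataset(
        config=config, islands=islands, calls=calls,
        truth=GroundTruth(pd.concat(truth_parts, ignore_index=True)),
        genes=genes, expression=expression, chrom_sizes=sizes,
        groups=cell_line_groups(config))


def write_dataset(dataset: SimulatedDataset, outdir) -> None:
    """Write every generated table in its on-disk format."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    irdm_io.write_cgi_track(dataset.islands, outdir / "cgi_track.bed")
    irdm_io.write_gene_models(dataset.genes, outdir / "genes.bed12")
    for (line, rep), df in dataset.calls.items():
        irdm_io.write_methylation(
            df, outdir / f"meth_{line}_rep{rep}.tsv")
    for line, df in dataset.expression.items():
        irdm_io.write_expression(df, outdir / f"expr_{line}.tsv")
    dataset.truth.table.to_csv(outdir / "ground_truth.tsv",
                               sep="\t", index=False)
    pd.Series(dataset.chrom_sizes, name="size").rename_axis("chrom") \
        .to_csv(outdir / "chrom_sizes.tsv", sep="\t")
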