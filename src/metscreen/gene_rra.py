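"""Gene-level significance by modified robust rank aggregation (alpha-RRA).

Each gene's sgRNAs occupy fractional ranks (percentiles) among all sgRNAs of
the screen.  Under the null those percentiles behave like uniform order
statistics, so for a gene with m sgRNAs at sorted percentiles r_1 <= ... <=
r_m the aggregation score is

    rho = min over {i : r_i <= alpha} of  P(U_(i) <= r_i)
        = min_i I_{r_i}(i, m - i + 1)

the minimum of regularized incomplete beta tails, restricted to sgRNAs
inside the top-alpha fraction (rho = 1 when none is).  rho is calibrated by
a seeded permutation null that reassigns percentiles to genes preserving
each gene's sgRNA count, with add-one p-values, Benjamini-Hochberg FDR, and
deterministic 1-based ranks per selection direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RRAConfig:
    """Aggregation settings.

    alpha
        fraction of the percentile scale counted as a "good" sgRNA rank
        (alpha = 1 recovers classic, cutoff-free rank aggregation).
    n_perm
        number of permutations for the gene-level null (>= 100).
    seed
        seed of the permutation stream.
    """

    alpha: float = 0.05
    n_perm: int = 1000
    seed: int = 0
    fdr_method: str = "benjamini_hochberg"

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.n_perm < 100:
            raise ValueError("n_perm must be at least 100")
        if self.fdr_method != "benjamini_hochberg":
            raise ValueError(f"unsupported fdr_method {self.fdr_method!r}")


def alpha_rra_score(percentiles, alpha: float) -> float:
    """alpha-RRA score of one gene from its sorted fractional sgRNA ranks."""
    r = np.asarray(percentiles, dtype=float)
    if r.ndim != 1 or len(r) == 0:
        raise ValueError("need a 1-D, non-empty percentile vector")
    if np.any(np.diff(r) < 0):
        raise ValueError("percentiles must be sorted ascending")
    if np.any(r <= 0) or np.any(r > 1):
        raise ValueError("percentiles must lie in (0, 1]")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    return float(_rho_sorted(r[None, :], alpha)[0])


def _rho_sorted(mat: np.ndarray, alpha: float) -> np.ndarray:
    """Row-wise rho for a (genes x m) matrix of sorted percentiles."""
    m = mat.shape[1]
    i = np.arange(1, m + 1, dtype=float)
    terms = special.betainc(i, m - i + 1, mat)
    terms = np.where(mat <= alpha, terms, np.inf)
    rho = terms.min(axis=1)
    return np.where(np.isfinite(rho), rho, 1.0)


def percentile_ranks(p: np.ndarray) -> np.ndarray:
    """Fractional ranks of raw p-values, average ties, scaled into (0, 1].

    Building gene aggregation from an external p-value vector (rather than a
    scored sgRNA table, whose strict ``rank_low``/``rank_high`` columns are
    preferred) uses these tie-averaged percentiles.
    """
    return stats.rankdata(p, method="average") / len(p)


def gene_pvalues(sgrna_table: pd.DataFrame, library,
                 config: RRAConfig) -> pd.DataFrame:
    """Aggregate per-sgRNA ranks into a per-gene result table.

    For each direction (neg from ``rank_low``, pos from ``rank_high``) computes
    rho, a permutation p-value, BH FDR and a 1-based rank.  Ranks order by
    ascending p, then rho, then the alpha=1 aggregation score (a continuous
    tie-break that keeps rank integers informative across the whole range),
    then gene id.  Genes of the library with no sgRNA in the table are
    excluded with a warning.  Results are invariant to the input row order
    and reproducible for a fixed seed.
    """
    genes_of = library.gene_of.reindex(sgrna_table.index)
    if genes_of.isna().any():
        missing = sgrna_table.index[genes_of.isna()][0]
        raise ValueError(f"sgRNA {missing!r} not present in library")
    absent = set(library.genes) - set(genes_of)
    if absent:
        logger.warning(
            "%d library genes have no sgRNA in this comparison and are "
            "excluded (first: %s)", len(absent), sorted(absent)[0],
        )

    # deterministic assignment order: sgRNAs sorted by (gene, sgRNA id)
    order = np.lexsort((sgrna_table.index.to_numpy(), genes_of.to_numpy()))
    genes_sorted = genes_of.to_numpy()[order]
    gene_ids, block_start, sizes = np.unique(
        genes_sorted, return_index=True, return_counts=True
    )
    n = len(sgrna_table)
    n_genes = len(gene_ids)

    # per-size index matrices: rows of flat positions into the assignment order
    size_groups: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for m in np.unique(sizes):
        rows = np.flatnonzero(sizes == m)
        idx = block_start[rows][:, None] + np.arange(m)[None, :]
        size_groups[int(m)] = (rows, idx)

    def _rho_all(perc_assigned: np.ndarray, alpha: float) -> np.ndarray:
        rho = np.empty(n_genes)
        for m, (rows, idx) in size_groups.items():
            rho[rows] = _rho_sorted(np.sort(perc_assigned[idx], axis=1), alpha)
        return rho

    perc = {
        "neg": (sgrna_table["rank_low"].to_numpy(dtype=float) / n)[order],
        "pos": (sgrna_table["rank_high"].to_numpy(dtype=float) / n)[order],
    }
    rho_obs = {d: _rho_all(perc[d], config.alpha) for d in ("neg", "pos")}
    rho_full = {d: _rho_all(perc[d], 1.0) for d in ("neg", "pos")}

    rng = np.random.default_rng(config.seed)
    hits = {d: np.zeros(n_genes) for d in ("neg", "pos")}
    for _ in range(config.n_perm):
        perm = rng.permutation(n)
        for d in ("neg", "pos"):
            hits[d] += _rho_all(perc[d][perm], config.alpha) <= rho_obs[d]

    out = pd.DataFrame(index=pd.Index(gene_ids, name="gene"))
    out["num"] = sizes
    for d in ("neg", "pos"):
        p = (1.0 + hits[d]) / (1.0 + config.n_perm)
        fdr = multipletests(p, method="fdr_bh")[1]
        rank_order = np.lexsort(
            (np.arange(n_genes), rho_full[d], rho_obs[d], p)
        )
        rank = np.empty(n_genes, dtype=np.int64)
        rank[rank_order] = np.arange(1, n_genes + 1)
        out[f"{d}_score"] = rho_obs[d]
        out[f"{d}_score_full"] = rho_full[d]
        out[f"{d}_p"] = p
        out[f"{d}_fdr"] = fdr
        out[f"{d}_rank"] = rank
    return out
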