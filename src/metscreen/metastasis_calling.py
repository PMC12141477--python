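"""Replicate integration and hit calling for in vivo metastasis screens.

The screen design: tumor cells carrying a genome-wide knockout library grow
as a primary tumor in each of several mice; metastases seeded in the lung
(and optionally liver) are sequenced alongside the matched primary tumor.
sgRNAs of a metastasis *suppressor* become enriched in metastases, so the
positive-selection direction is the default readout.

This module implements the study-level logic on top of per-mouse gene
results:

* pick the replicate mice with the strongest lung tropism,
* collapse per-mouse FDR-adjusted p-values into per-gene "essentiality
  scores" (``-log10`` of the smallest adjusted p across selected mice) and a
  final ranking,
* intersect hits across two cell lines (concordance),
* the alternative lung-vs-liver rank filter that keeps genes acting on lung
  but not liver colonization in every replicate, with Fisher-combined
  evidence across replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gene_rra import RRAConfig, gene_pvalues
from .screen_io import NormalizedCounts, SgRNALibrary, median_ratio_normalize
from .sgrna_stats import fit_variance_model, score_sgrnas_paired

logger = logging.getLogger(__name__)


@dataclass
class MouseComparisonSet:
    """Per-mouse gene results for one cell line.

    ``lung`` / ``liver`` map mouse id to the GeneResult table of the
    corresponding met-vs-primary comparison; ``lung_preference`` maps mouse
    id to the fraction of metastatic burden found in the lung (simulators
    provide the ground-truth value, real screens an imaging-derived one).
    """

    cell_line: str
    lung: dict[str, pd.DataFrame]
    liver: dict[str, pd.DataFrame] = field(default_factory=dict)
    lung_preference: dict[str, float] = field(default_factory=dict)

    @property
    def mice(self) -> list[str]:
        return sorted(self.lung)


def select_mice(comparisons: MouseComparisonSet, k: int) -> list[str]:
    """The k mice with the largest lung preference (ties by mouse id)."""
    mice = comparisons.mice
    if len(mice) < k:
        logger.warning(
            "only %d mice available (< %d requested); using all", len(mice), k
        )
        k = len(mice)
    pref = comparisons.lung_preference
    ordered = sorted(mice, key=lambda m: (-pref.get(m, 0.0), m))
    return ordered[:k]


def essentiality_scores(comparisons: MouseComparisonSet,
                        selected_mice: Sequence[str],
                        direction: str = "pos") -> pd.DataFrame:
    """Per-gene essentiality table over the selected replicate mice.

    For each gene the smallest ``direction`` FDR-adjusted p across the
    selected mice is the representative value; the essentiality score is
    ``-log10`` of it and the final rank orders genes by ascending minimum
    adjusted p.  Adjusted p-values saturate at the permutation resolution,
    so rank ties are broken by the smallest raw p, then the smallest
    aggregation score, then gene id.  A gene missing from a mouse is treated
    as p = 1 there (logged).
    """
    if direction not in ("pos", "neg"):
        raise ValueError("direction must be 'pos' or 'neg'")
    if not selected_mice:
        raise ValueError("no mice selected")
    tables = {}
    for mouse in selected_mice:
        if mouse not in comparisons.lung:
            raise ValueError(f"mouse {mouse!r} has no lung-vs-primary result")
        tables[mouse] = comparisons.lung[mouse]

    genes = sorted(set().union(*(t.index for t in tables.values())))
    gidx = pd.Index(genes, name="gene")
    padj = pd.DataFrame(index=gidx)
    praw = pd.DataFrame(index=gidx)
    rho = pd.DataFrame(index=gidx)
    for mouse, tab in tables.items():
        missing = len(gidx.difference(tab.index))
        if missing:
            logger.warning(
                "%d genes missing from mouse %s; treated as p = 1", missing, mouse
            )
        padj[mouse] = tab[f"{direction}_fdr"].reindex(gidx).fillna(1.0)
        praw[mouse] = tab[f"{direction}_p"].reindex(gidx).fillna(1.0)
        rho[mouse] = tab[f"{direction}_score"].reindex(gidx).fillna(1.0)

    out = padj.add_prefix("padj_")
    out["min_adj_p"] = padj.min(axis=1)
    out["essentiality_score"] = -np.log10(out["min_adj_p"]) + 0.0  # avoid -0.0
    keys = np.lexsort((
        np.arange(len(gidx)),
        rho.min(axis=1).to_numpy(),
        praw.min(axis=1).to_numpy(),
        out["min_adj_p"].to_numpy(),
    ))
    rank = np.empty(len(gidx), dtype=np.int64)
    rank[keys] = np.arange(1, len(gidx) + 1)
    out["final_rank"] = rank
    return out


@dataclass(frozen=True)
class ConcordanceResult:
    """Genes significant in both cell lines, with combined (worst) ranks."""

    concordant: list[str]
    combined_rank: pd.Series
    top_k: list[str]


def cross_line_concordance(table_a: pd.DataFrame, table_b: pd.DataFrame,
                           sig_threshold: float = 0.05,
                           k: int = 10) -> ConcordanceResult:
    """Intersect hits of two cell lines' essentiality tables.

    Concordant genes have ``min_adj_p <= sig_threshold`` in both lines.  The
    combined rank is the worse (max) of the two per-line final ranks, so a
    top gene must rank well in both lines; ``top_k`` keeps the k best
    combined ranks among concordant genes that sit inside the per-line top-k
    of *each* line.
    """
    shared = table_a.index.intersection(table_b.index)
    if len(shared) == 0:
        raise ValueError("cell lines have disjoint gene universes")
    a = table_a.loc[shared]
    b = table_b.loc[shared]
    concordant = sorted(
        shared[(a["min_adj_p"] <= sig_threshold)
               & (b["min_adj_p"] <= sig_threshold)]
    )
    combined = pd.concat(
        [a["final_rank"], b["final_rank"]], axis=1
    ).max(axis=1).astype(np.int64)
    combined.name = "combined_rank"
    in_both_top = set(shared[(a["final_rank"] <= k) & (b["final_rank"] <= k)])
    candidates = [g for g in concordant if g in in_both_top]
    top_k = sorted(candidates, key=lambda g: (combined[g], g))[:k]
    return ConcordanceResult(concordant=concordant,
                             combined_rank=combined.sort_index(),
                             top_k=top_k)


def lung_liver_rank_filter(comparisons: MouseComparisonSet,
                           direction: str = "pos") -> pd.DataFrame:
    """Keep genes that act on lung, but not liver, metastasis in every mouse.

    Reading the 1-based report ranks numerically (1 = most significant), a
    gene passes in a mouse iff its depletion rank for the lung comparison
    exceeds the liver one (``neg_rank(lung) > neg_rank(liver)``: less
    depleted in lung) while its enrichment rank is simultaneously smaller
    (``pos_rank(lung) < pos_rank(liver)``: more enriched in lung).  Overall
    passing requires the inequalities in all replicate mice.  For passing
    genes the lung p-values of ``direction`` are combined across replicates
    by Fisher's method, and ``comprehensive_rank`` orders passing genes by
    that combined evidence (ties by gene id).
    """
    if direction not in ("pos", "neg"):
        raise ValueError("direction must be 'pos' or 'neg'")
    mice = comparisons.mice
    if not mice:
        raise ValueError("no lung comparisons present")
    for mouse in mice:
        if mouse not in comparisons.liver:
            raise ValueError(f"mouse {mouse!r} has no liver-vs-primary result")

    genes = comparisons.lung[mice[0]].index.sort_values()
    out = pd.DataFrame(index=pd.Index(genes, name="gene"))
    log_p = np.zeros(len(genes))
    passes = np.ones(len(genes), dtype=bool)
    for mouse in mice:
        lung = comparisons.lung[mouse].reindex(genes)
        liver = comparisons.liver[mouse].reindex(genes)
        for tab, organ in ((lung, "lung"), (liver, "liver")):
            if tab[["neg_rank", "pos_rank"]].isna().any().any():
                raise ValueError(
                    f"{organ} result of mouse {mouse!r} does not cover the "
                    "shared gene universe"
                )
        ok = ((lung["neg_rank"] > liver["neg_rank"])
              & (lung["pos_rank"] < liver["pos_rank"])).to_numpy()
        out[f"pass_{mouse}"] = ok
        passes &= ok
        log_p += np.log(lung[f"{direction}_p"].to_numpy())

    out["passes_filter"] = passes
    out["combined_p"] = stats.chi2.sf(-2.0 * log_p, df=2 * len(mice))
    rank = np.full(len(genes), np.nan)
    passing = np.flatnonzero(passes)
    order = passing[np.lexsort((genes[passing].to_numpy(),
                                out["combined_p"].to_numpy()[passing]))]
    rank[order] = np.arange(1, len(passing) + 1)
    out["comprehensive_rank"] = rank
    logger.info(
        "lung/liver filter: %d of %d genes pass in all %d mice",
        len(passing), len(genes), len(mice),
    )
    return out


def build_comparison_set(counts: pd.DataFrame, library: SgRNALibrary,
                         meta: pd.DataFrame, cell_line: str,
                         config: RRAConfig,
                         include_liver: bool = False,
                         lung_preference: Mapping[str, float] | None = None,
                         pseudocount: float = 1.0) -> MouseComparisonSet:
    """Run the per-mouse stages of the pipeline for one cell line.

    Normalizes the cell line's samples together, fits the mean-variance
    model on the primary-tumor replicates, then scores each mouse's paired
    lung (and optionally liver) comparison and aggregates it to gene level.
    """
    sub = meta[(meta["cell_line"] == cell_line)
               & meta.index.isin(counts.columns)]
    if sub.empty:
        raise ValueError(f"no samples of cell line {cell_line!r} in count table")
    norm = median_ratio_normalize(counts[list(sub.index)])
    controls = sorted(sub.index[sub["tissue"] == "primary"])
    model = fit_variance_model(norm, controls)
    logger.info("cell line %s: variance model k=%.4g b=%.3f over %d controls",
                cell_line, model.k, model.b, len(controls))

    mice = sorted(sub.loc[sub["tissue"] == "primary", "mouse_id"].unique())
    lung: dict[str, pd.DataFrame] = {}
    liver: dict[str, pd.DataFrame] = {}
    tissues = [("lung_met", lung)] + ([("liver_met", liver)] if include_liver else [])
    for mouse in mice:
        for tissue, store in tissues:
            sg = score_sgrnas_paired(norm, model, sub, mouse,
                                     treatment_tissue=tissue,
                                     pseudocount=pseudocount)
            store[mouse] = gene_pvalues(sg, library, config)
    pref = dict(lung_preference) if lung_preference else {}
    return MouseComparisonSet(cell_line=cell_line, lung=lung, liver=liver,
                              lung_preference=pref)


def analyze_cell_line(counts: pd.DataFrame, library: SgRNALibrary,
                      meta: pd.DataFrame, cell_line: str, config: RRAConfig,
                      k_mice: int = 4, direction: str = "pos",
                      lung_preference: Mapping[str, float] | None = None,
                      ) -> tuple[MouseComparisonSet, pd.DataFrame]:
    """Full main analysis for one cell line: paired scoring through ranking."""
    comparisons = build_comparison_set(
        counts, library, meta, cell_line, config,
        lung_preference=lung_preference,
    )
    selected = select_mice(comparisons, k_mice)
    logger.info("cell line %s: selected mice %s", cell_line, selected)
    table = essentiality_scores(comparisons, selected, direction=direction)
    return comparisons, table
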