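"""Generative model of an in vivo pooled CRISPR screen with ground truth.

The simulator mirrors the experimental pipeline of a transplantation
metastasis screen: a plasmid library with log-normal sgRNA abundances is
transduced at low MOI into tumor cells, replicate mice each receive a
founder population kept at high per-sgRNA coverage, primary tumors grow
with clonal (gamma-multiplicative) noise, and each organ is seeded through
a tight per-cell Bernoulli bottleneck before metastatic outgrowth and
sequencing.  Knockout of a planted suppressor gene multiplies the seeding
probability of its sgRNAs in the corresponding organ, so lung-specific
suppressors become enriched in lung metastases relative to the matched
primary tumor.

All randomness flows from one master seed through `numpy.random.SeedSequence`
spawning: stream 0 draws the plasmid library, stream 1+i drives everything
within mouse i.  Outputs are byte-identical across runs for a fixed seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .screen_io import SgRNALibrary

logger = logging.getLogger(__name__)


@dataclass
class ScreenSimConfig:
    """Simulation settings; defaults are a desk-scale GeCKO-like screen.

    ``suppressors`` maps gene id to ``(lung_effect, liver_effect)``
    multipliers (>= 1) on the per-cell organ-seeding probability.
    ``cells_per_mouse`` defaults to the smallest population giving
    ``target_coverage`` infected cells per sgRNA at the configured MOI;
    ``seq_depth`` defaults to 300 reads per sgRNA per sample.
    """

    n_genes: int = 2000
    sgrnas_per_gene: int = 4
    n_mice: int = 5
    moi: float = 0.3
    cells_per_mouse: int | None = None
    target_coverage: float = 200.0
    suppressors: dict[str, tuple[float, float]] = field(default_factory=dict)
    base_seed_prob_lung: float = 0.03
    base_seed_prob_liver: float = 0.01
    bottleneck_lung: int = 20_000
    bottleneck_liver: int = 20_000
    growth_dispersion: float = 0.2
    plasmid_sigma: float = 0.5
    seq_depth: int | None = None
    cell_line: str = "SIM1"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.moi <= 1:
            raise ValueError("moi must be in (0, 1]")
        if self.n_genes < 1 or self.sgrnas_per_gene < 1 or self.n_mice < 1:
            raise ValueError("n_genes, sgrnas_per_gene, n_mice must be positive")
        for gene, (le, ve) in self.suppressors.items():
            if le < 1 or ve < 1:
                raise ValueError(
                    f"suppressor {gene!r} effects must be >= 1, got ({le}, {ve})"
                )
        if self.coverage < 1:
            raise ValueError(f"per-sgRNA coverage {self.coverage:.2f} is below 1")

    @property
    def n_sgrna(self) -> int:
        return self.n_genes * self.sgrnas_per_gene

    @property
    def resolved_cells_per_mouse(self) -> int:
        if self.cells_per_mouse is not None:
            return self.cells_per_mouse
        return math.ceil(self.target_coverage * self.n_sgrna / self.moi)

    @property
    def resolved_seq_depth(self) -> int:
        return self.seq_depth if self.seq_depth is not None else 300 * self.n_sgrna

    @property
    def coverage(self) -> float:
        """Expected infected cells per sgRNA per mouse."""
        return self.resolved_cells_per_mouse * self.moi / self.n_sgrna

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def library(self) -> SgRNALibrary:
        mapping = {
            f"{g}_sg{j}": g
            for g in self.gene_ids()
            for j in range(1, self.sgrnas_per_gene + 1)
        }
        return SgRNALibrary.from_mapping(mapping)


@dataclass(frozen=True)
class ScreenTruth:
    """Ground truth of a simulated screen.

    ``genes``: per gene is_suppressor, lung_effect, liver_effect.
    ``mice``: per mouse realized lung/liver seeding burden and
    ``lung_preference`` = lung / (lung + liver) burden.
    """

    genes: pd.DataFrame
    mice: pd.DataFrame

    @property
    def suppressor_genes(self) -> list[str]:
        return sorted(self.genes.index[self.genes["is_suppressor"]])

    @property
    def lung_preference(self) -> dict[str, float]:
        return self.mice["lung_preference"].to_dict()


def benchmark_config(n_suppressors: int = 20, lung_effect: float = 10.0,
                     liver_effect: float = 1.0, seed: int = 1,
                     **overrides) -> ScreenSimConfig:
    """Default benchmark: planted lung-metastasis suppressors at fixed effect.

    Suppressor genes are drawn (seeded) from the gene universe; pass any
    :class:`ScreenSimConfig` field as an override.
    """
    cfg = ScreenSimConfig(seed=seed, **overrides)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7_919]))
    picked = rng.choice(cfg.gene_ids(), size=n_suppressors, replace=False)
    cfg.suppressors = {g: (lung_effect, liver_effect) for g in sorted(picked)}
    return cfg


def _effect_vectors(config: ScreenSimConfig, genes_per_sgrna: np.ndarray):
    lung = np.ones(config.n_sgrna)
    liver = np.ones(config.n_sgrna)
    for gene, (le, ve) in config.suppressors.items():
        mask = genes_per_sgrna == gene
        if not mask.any():
            raise ValueError(f"suppressor gene {gene!r} not in gene universe")
        lung[mask] = le
        liver[mask] = ve
    return lung, liver


def simulate_screen(config: ScreenSimConfig
                    ) -> tuple[pd.DataFrame, pd.DataFrame, ScreenTruth]:
    """Simulate one cell line's screen.

    Returns ``(counts, meta, truth)``: an sgRNA x sample integer count
    table (primary, lung_met and liver_met per mouse), the matching sample
    metadata, and the ground truth.  Deterministic given ``config.seed``.
    """
    library = config.library()
    sgrnas = library.sgrna_ids.to_numpy()
    genes_per_sgrna = library.gene_of.to_numpy()
    n = config.n_sgrna
    depth = config.resolved_seq_depth
    d = config.growth_dispersion
    lung_eff, liver_eff = _effect_vectors(config, genes_per_sgrna)

    streams = np.random.SeedSequence(config.seed).spawn(1 + config.n_mice)
    rng0 = np.random.default_rng(streams[0])
    plasmid = rng0.lognormal(mean=0.0, sigma=config.plasmid_sigma, size=n)
    plasmid_prob = plasmid / plasmid.sum()

    n_infected = int(round(config.resolved_cells_per_mouse * config.moi))
    organs = (
        ("lung_met", config.base_seed_prob_lung, lung_eff, config.bottleneck_lung),
        ("liver_met", config.base_seed_prob_liver, liver_eff,
         config.bottleneck_liver),
    )

    counts: dict[str, np.ndarray] = {}
    meta_rows: dict[str, dict] = {}
    mice_rows = {}
    width = len(str(config.n_mice))
    for i in range(config.n_mice):
        mouse = f"m{i + 1:0{width}d}"
        rng = np.random.default_rng(streams[1 + i])
        founders = rng.multinomial(n_infected, plasmid_prob)
        growth = rng.gamma(shape=1.0 / d, scale=d, size=n)
        primary_ab = founders * growth
        primary_cells = np.rint(primary_ab).astype(np.int64)

        def _sample_name(tissue: str) -> str:
            return f"{config.cell_line}_{mouse}_{tissue}"

        def _sequence(abundance: np.ndarray) -> np.ndarray:
            total = abundance.sum()
            if total <= 0:
                return np.zeros(n, dtype=np.int64)
            return rng.multinomial(depth, abundance / total)

        counts[_sample_name("primary")] = _sequence(primary_ab)
        meta_rows[_sample_name("primary")] = {
            "cell_line": config.cell_line, "mouse_id": mouse, "tissue": "primary",
        }

        burdens = {}
        for tissue, base_prob, eff, bottleneck in organs:
            p_seed = np.clip(base_prob * eff, 0.0, 1.0)
            seeds = rng.binomial(primary_cells, p_seed)
            burden = int(seeds.sum())
            burdens[tissue] = burden
            if burden == 0:
                logger.warning(
                    "mouse %s: zero cells seeded the %s; emitting an all-zero "
                    "sample", mouse, tissue,
                )
                reads = np.zeros(n, dtype=np.int64)
            else:
                if burden > bottleneck:
                    seeds = rng.multinomial(bottleneck, seeds / burden)
                outgrowth = rng.gamma(shape=1.0 / d, scale=d, size=n)
                reads = _sequence(seeds * outgrowth)
            counts[_sample_name(tissue)] = reads
            meta_rows[_sample_name(tissue)] = {
                "cell_line": config.cell_line, "mouse_id": mouse, "tissue": tissue,
            }

        lung_b, liver_b = burdens["lung_met"], burdens["liver_met"]
        total_b = lung_b + liver_b
        mice_rows[mouse] = {
            "lung_burden": lung_b,
            "liver_burden": liver_b,
            "lung_preference": lung_b / total_b if total_b > 0 else 0.5,
        }

    count_table = pd.DataFrame(counts, index=pd.Index(sgrnas, name="sgRNA"))
    meta = pd.DataFrame.from_dict(meta_rows, orient="index")
    meta.index.name = "sample_id"

    gene_ids = config.gene_ids()
    truth_genes = pd.DataFrame(
        {
            "is_suppressor": [g in config.suppressors for g in gene_ids],
            "lung_effect": [config.suppressors.get(g, (1.0, 1.0))[0]
                            for g in gene_ids],
            "liver_effect": [config.suppressors.get(g, (1.0, 1.0))[1]
                             for g in gene_ids],
        },
        index=pd.Index(gene_ids, name="gene"),
    )
    truth_mice = pd.DataFrame.from_dict(mice_rows, orient="index")
    truth_mice.index.name = "mouse_id"
    return count_table, meta, ScreenTruth(genes=truth_genes, mice=truth_mice)


def recovery_metrics(ranking: pd.DataFrame, truth: ScreenTruth,
                     top_fraction: float = 0.01,
                     rank_col: str = "final_rank") -> dict[str, float]:
    """Precision/recall of the planted suppressors at a top rank fraction.

    ``ranking`` is an essentiality table (``final_rank``) or a filter table
    (``comprehensive_rank``); genes without a rank (NaN) are never counted
    as recovered.  The mean rank of planted genes uses, for unranked genes,
    one past the number of ranked genes.
    """
    planted = truth.suppressor_genes
    if not planted:
        raise ValueError("truth contains no planted suppressor genes")
    if rank_col not in ranking.columns:
        raise ValueError(f"ranking table has no column {rank_col!r}")
    ranks = ranking[rank_col]
    n_universe = len(ranking)
    top_n = max(1, int(math.floor(top_fraction * n_universe)))
    top_genes = set(ranking.index[ranks.notna() & (ranks <= top_n)])
    hit = len(top_genes & set(planted))
    worst = int(ranks.max()) + 1 if ranks.notna().any() else 1
    planted_ranks = ranks.reindex(planted).fillna(worst)
    return {
        "precision": hit / len(top_genes) if top_genes else 0.0,
        "recall": hit / len(planted),
        "mean_planted_rank": float(planted_ranks.mean()),
        "top_n": float(top_n),
    }
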