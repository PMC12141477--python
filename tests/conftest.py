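import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import metscreen as ms

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def tiny_library() -> ms.SgRNALibrary:
    return ms.SgRNALibrary.from_mapping({
        "sgA1": "GENEA", "sgA2": "GENEA",
        "sgB1": "GENEB", "sgB2": "GENEB",
        "sgC1": "GENEC",
    })


@pytest.fixture
def small_screen():
    """A small simulated screen with two planted lung suppressors."""
    cfg = ms.ScreenSimConfig(n_genes=60, sgrnas_per_gene=2, n_mice=3, seed=12,
                             suppressors={"G10": (30.0, 1.0), "G20": (30.0, 1.0)})
    counts, meta, truth = ms.simulate_screen(cfg)
    return cfg, counts, meta, truth


def make_norm(values: np.ndarray, columns=None, index=None) -> ms.NormalizedCounts:
    """Wrap a raw array as NormalizedCounts with unit size factors."""
    values = np.asarray(values, dtype=float)
    columns = columns or [f"s{j}" for j in range(values.shape[1])]
    index = index or [f"sg{i:05d}" for i in range(values.shape[0])]
    frame = pd.DataFrame(values, index=index, columns=columns)
    return ms.NormalizedCounts(values=frame,
                               size_factors=pd.Series(1.0, index=frame.columns))


def make_gene_result(table: dict[str, dict[str, float]],
                     direction: str = "pos") -> pd.DataFrame:
    """Build a minimal GeneResult frame from {gene: {field: value}}.

    Fields not given are derived: p defaults to fdr, score to p, ranks to
    the order of p (ties by gene id).
    """
    genes = sorted(table)
    out = pd.DataFrame(index=pd.Index(genes, name="gene"))
    out["num"] = [table[g].get("num", 2) for g in genes]
    for d in ("neg", "pos"):
        fdr = np.array([table[g].get(f"{d}_fdr", 1.0) for g in genes])
        p = np.array([table[g].get(f"{d}_p", f) for g, f in zip(genes, fdr)])
        rho = np.array([table[g].get(f"{d}_score", v) for g, v in zip(genes, p)])
        out[f"{d}_score"] = rho
        out[f"{d}_score_full"] = rho
        out[f"{d}_p"] = p
        out[f"{d}_fdr"] = fdr
        if any(f"{d}_rank" in table[g] for g in genes):
            out[f"{d}_rank"] = [table[g][f"{d}_rank"] for g in genes]
        else:
            order = np.lexsort((np.array(genes), p))
            rank = np.empty(len(genes), dtype=np.int64)
            rank[order] = np.arange(1, len(genes) + 1)
            out[f"{d}_rank"] = rank
    return out
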