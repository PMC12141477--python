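"""Per-sgRNA enrichment statistics for paired metastasis-vs-primary tests.

The model is the standard screen-analysis one: a negative binomial whose
mean is the (pseudocounted) control abundance of the sgRNA and whose
variance follows an empirical mean-variance law ``var(mu) = mu + k * mu**b``
fitted across control replicates.  For each sgRNA in a mouse the metastasis
count is treated as a draw from that null and scored with exact NB tail
probabilities in both directions:

* ``p_high = P(X >= t)`` - enrichment in the metastasis (positive selection;
  the direction in which knockouts of a metastasis *suppressor* move),
* ``p_low = P(X <= t)`` - depletion (negative selection),

with ``t`` the treatment value rounded to the nearest integer so the tails
are exact.  When the fitted variance does not exceed the mean the Poisson
tail is used instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Quadratic overdispersion used when the mean-variance law cannot be fitted.
FALLBACK_K = 0.01
FALLBACK_B = 2.0


@dataclass(frozen=True)
class VarianceModel:
    """Mean-variance law ``var(mu) = mu + k * mu**b`` (k > 0)."""

    k: float
    b: float

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError("overdispersion coefficient k must be positive")

    def variance(self, mu):
        mu = np.asarray(mu, dtype=float)
        return mu + self.k * np.power(mu, self.b)


def fit_variance_model(norm, control_samples: Sequence[str],
                       fallback_k: float = FALLBACK_K,
                       min_points: int = 10, n_bins: int = 20) -> VarianceModel:
    """Fit (k, b) by regressing log(var - mean) on log(mean).

    ``norm`` is a :class:`~metscreen.screen_io.NormalizedCounts`;
    ``control_samples`` names >= 2 of its columns.  Per-sgRNA sample
    variances are extremely noisy with few replicates, so sgRNAs are pooled
    into up to ``n_bins`` abundance-quantile bins; within each bin the mean
    of the per-sgRNA means and of the per-sgRNA variances define one
    regression point, and only bins with pooled var > mean contribute.

    Fallback (``var = mu + fallback_k * mu**2``, logged) is used when there
    is a single control sample, when fewer than ``min_points`` sgRNAs have
    var > mean, or when the data carry no material overdispersion (mean
    var/mean ratio below 1.1, as for Poisson-like counts).
    """
    cols = list(control_samples)
    if len(cols) < 1:
        raise ValueError("need at least one control sample")
    vals = norm.values[cols].to_numpy(dtype=float)
    if vals.shape[1] < 2:
        logger.warning(
            "single control sample: using fallback variance model "
            "var = mu + %.3g * mu^2", fallback_k,
        )
        return VarianceModel(k=fallback_k, b=FALLBACK_B)
    mean = vals.mean(axis=1)
    var = vals.var(axis=1, ddof=1)
    pos = mean > 0
    n_over = int(((var > mean) & pos).sum())
    dispersion_ratio = float(np.mean(var[pos] / mean[pos])) if pos.any() else 0.0
    if n_over < min_points or dispersion_ratio < 1.1:
        logger.warning(
            "no usable overdispersion signal (%d sgRNAs with var > mean, "
            "mean var/mean %.3f): using fallback variance model "
            "var = mu + %.3g * mu^2", n_over, dispersion_ratio, fallback_k,
        )
        return VarianceModel(k=fallback_k, b=FALLBACK_B)

    order = np.argsort(mean[pos])
    m_sorted = mean[pos][order]
    v_sorted = var[pos][order]
    n_bins = max(2, min(n_bins, len(m_sorted) // max(min_points // 2, 2)))
    splits = np.array_split(np.arange(len(m_sorted)), n_bins)
    bin_mean = np.array([m_sorted[s].mean() for s in splits if len(s)])
    bin_var = np.array([v_sorted[s].mean() for s in splits if len(s)])
    informative = bin_var > bin_mean
    if int(informative.sum()) < 2:
        logger.warning(
            "fewer than 2 informative abundance bins: using fallback "
            "variance model var = mu + %.3g * mu^2", fallback_k,
        )
        return VarianceModel(k=fallback_k, b=FALLBACK_B)
    b, log_k = np.polyfit(np.log(bin_mean[informative]),
                          np.log(bin_var[informative] - bin_mean[informative]), 1)
    return VarianceModel(k=float(np.exp(log_k)), b=float(b))


def _nb_tails(t: np.ndarray, mu: np.ndarray, var: np.ndarray):
    """Exact lower/upper tail probabilities at integer t.

    NB parameterized by mean mu and variance var via size r = mu^2/(var-mu);
    Poisson when var <= mu.
    """
    p_low = np.empty_like(mu)
    p_high = np.empty_like(mu)
    over = var > mu
    if over.any():
        r = mu[over] ** 2 / (var[over] - mu[over])
        q = r / (r + mu[over])  # scipy's success probability
        p_high[over] = stats.nbinom.sf(t[over] - 1, r, q)
        p_low[over] = stats.nbinom.cdf(t[over], r, q)
    if (~over).any():
        p_high[~over] = stats.poisson.sf(t[~over] - 1, mu[~over])
        p_low[~over] = stats.poisson.cdf(t[~over], mu[~over])
    return p_low, p_high


def score_sgrnas_paired(norm, model: VarianceModel, meta: pd.DataFrame,
                        mouse_id: str,
                        treatment_tissue: str = "lung_met",
                        control_tissue: str = "primary",
                        pseudocount: float = 1.0) -> pd.DataFrame:
    """Score every sgRNA for one paired within-mouse comparison.

    Looks up the two samples of ``mouse_id`` in ``meta`` (restricted to the
    columns of ``norm``), builds the NB null from the control abundance plus
    ``pseudocount`` and the fitted variance model, and returns a table with
    columns control_mean, treatment, score, p_low, p_high, rank_low,
    rank_high.  Ranks are 1-based permutations of 1..n_sgRNA, ordered by the
    corresponding p-value.  Ties - unavoidable with exact discrete tails,
    e.g. every zero-count sgRNA has p_high exactly 1 - are broken by the
    continuous z-score (a zero is more depleted the larger its control
    mean), then by sgRNA id, so ranks stay informative under heavy dropout.
    """
    def _sample_for(tissue: str) -> str:
        hit = meta[(meta["mouse_id"] == mouse_id) & (meta["tissue"] == tissue)]
        hit = hit[hit.index.isin(norm.values.columns)]
        if len(hit) == 0:
            raise ValueError(f"mouse {mouse_id!r} has no {tissue!r} sample")
        if len(hit) > 1:
            raise ValueError(
                f"mouse {mouse_id!r} has {len(hit)} {tissue!r} samples; "
                "expected exactly one"
            )
        return hit.index[0]

    control = _sample_for(control_tissue)
    treatment = _sample_for(treatment_tissue)

    mu = norm.values[control].to_numpy(dtype=float) + pseudocount
    t = np.rint(norm.values[treatment].to_numpy(dtype=float)).astype(np.int64)
    var = model.variance(mu)
    p_low, p_high = _nb_tails(t, mu, var)
    score = (t - mu) / np.sqrt(var)

    idx = norm.values.index
    n = len(idx)

    def _ranks(p: np.ndarray, tiebreak: np.ndarray) -> np.ndarray:
        order = np.lexsort((idx.to_numpy(), tiebreak, p))
        ranks = np.empty(n, dtype=np.int64)
        ranks[order] = np.arange(1, n + 1)
        return ranks

    out = pd.DataFrame(
        {
            "control_mean": mu,
            "treatment": t,
            "score": score,
            "p_low": p_low,
            "p_high": p_high,
            "rank_low": _ranks(p_low, score),
            "rank_high": _ranks(p_high, -score),
        },
        index=idx,
    )
    out.attrs["comparison"] = {
        "mouse_id": mouse_id,
        "treatment_tissue": treatment_tissue,
        "control_tissue": control_tissue,
        "treatment_sample": treatment,
        "control_sample": control,
    }
    return out
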