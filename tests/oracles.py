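"""Independent reference computations used by the test suite.

These deliberately avoid the code paths they check: negative-binomial tails
are summed term by term from the log-pmf, order-statistic CDFs are obtained
by numerical integration of the density, and permutation p-values are
enumerated exhaustively over all rank assignments.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.integrate import quad
from scipy.special import gammaln


def nb_tail_upper(t: int, mu: float, var: float, tol: float = 1e-16) -> float:
    """P(X >= t) for NB(mean mu, variance var) by direct pmf summation."""
    r = mu ** 2 / (var - mu)
    q = r / (r + mu)  # success probability, pmf ~ C(x+r-1, x) q^r (1-q)^x

    def log_pmf(x: int) -> float:
        return (gammaln(x + r) - gammaln(r) - gammaln(x + 1)
                + r * math.log(q) + x * math.log1p(-q))

    total = 0.0
    x = t
    while True:
        term = math.exp(log_pmf(x))
        total += term
        if term < tol and x > mu + 20 * math.sqrt(var):
            return total
        x += 1


def order_stat_cdf(r: float, i: int, m: int) -> float:
    """P(U_(i) <= r) for the i-th of m uniform order statistics, by quadrature."""
    coef = (math.factorial(m)
            / (math.factorial(i - 1) * math.factorial(m - i)))
    val, _ = quad(lambda x: coef * x ** (i - 1) * (1 - x) ** (m - i), 0.0, r)
    return val


def rho_reference(sorted_percentiles, alpha: float) -> float:
    """alpha-RRA score via closed-form beta order-statistic CDFs (m <= 4)."""
    r = list(sorted_percentiles)
    m = len(r)
    closed = {
        1: lambda x: 1 - (1 - x) ** m,              # i = 1
        m: lambda x: x ** m,                         # i = m
    }
    terms = []
    for i, ri in enumerate(r, start=1):
        if ri > alpha:
            continue
        if i in closed:
            terms.append(closed[i](ri))
        elif (m, i) == (3, 2):
            terms.append(ri ** 2 * (3 - 2 * ri))
        elif (m, i) == (4, 2):
            terms.append(ri ** 2 * (6 - 8 * ri + 3 * ri ** 2))
        elif (m, i) == (4, 3):
            terms.append(ri ** 3 * (4 - 3 * ri))
        else:
            terms.append(order_stat_cdf(ri, i, m))
    return min(terms) if terms else 1.0


def enumerate_gene_pvalues(percentiles: np.ndarray, m: int,
                           rho_obs: float, alpha: float) -> float:
    """Exact P(rho_perm <= rho_obs) for one gene of m sgRNAs.

    Under a random reassignment of the n percentiles to genes preserving
    sgRNA counts, a gene's set is marginally a uniform m-subset, so the
    exact null enumerates all C(n, m) subsets.
    """
    hits = 0
    total = 0
    for subset in itertools.combinations(sorted(percentiles), m):
        total += 1
        if rho_reference(subset, alpha) <= rho_obs + 1e-12:
            hits += 1
    return hits / total
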