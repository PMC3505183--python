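"""Audic-Claverie exact test for tag counts and Benjamini-Hochberg FDR.

For a gene with x tags in a library of N1 clean tags, the probability of
observing y tags in a second library of N2 clean tags, under the null of
equal underlying expression, is

    p(y | x) = (N2/N1)^y * (x+y)! / ( x! * y! * (1 + N2/N1)^(x+y+1) )

— a negative-binomial mass in y that sums exactly to one (the exponent
x+y+1 matters: the variant without the +1, seen in some reprints, does not
normalize). All evaluation is in log-space via log-gamma; naive factorials
overflow long before realistic tag counts.

The two-sided p-value doubles the smaller of the two opposing tails —
P(Y >= y | x) and, with the libraries' roles exchanged, P(X >= x | y) —
both including the observed count, capped at 1. These are exactly the two
tails of the binomial distribution of y given the total x + y (success
probability N2/(N1+N2)), so the p-value is exactly invariant under
exchanging (x, N1) with (y, N2); conditioning both tails on the same
observed x instead would break that exchange symmetry by one point mass at
small counts. Significance for DE calling uses the
conventional thresholds FDR <= 0.001 and |log2 ratio| >= 1, the ratio taken
on floored TPMs so genes absent from one library still get a direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

from .types import ExpressionMatrix


def _log_mass(ys: np.ndarray, x: int, log_r: float) -> np.ndarray:
    ys = np.asarray(ys, dtype=float)
    return (
        ys * log_r
        + gammaln(x + ys + 1)
        - gammaln(x + 1)
        - gammaln(ys + 1)
        - (x + ys + 1) * np.log1p(np.exp(log_r))
    )


def ac_mass(y: int, x: int, n1: int, n2: int) -> float:
    """p(y | x) for library totals N1, N2 (log-space evaluation)."""
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    log_r = math.log(n2) - math.log(n1)
    return float(np.exp(_log_mass(np.array([y]), x, log_r)[0]))


def _upper_tail(x: int, y: int, n1: int, n2: int) -> float:
    """P(Y >= y | x): the mass is negative-binomial in y (x+1 successes at
    probability N1/(N1+N2)), whose tail equals the binomial tail
    P(Bin(x+y, N2/(N1+N2)) >= y) exactly — evaluated via the regularized
    incomplete beta function, stable at any N2/N1 ratio."""
    if y == 0:
        return 1.0
    q = n2 / (n1 + n2)
    return float(sps.binom.sf(y - 1, x + y, q))


def ac_pvalue_two_sided(x: int, y: int, n1: int, n2: int) -> float:
    """Two-sided p: min(1, 2 * min(P(Y>=y|x), P(X>=x|y))).

    The second tail is the first with the libraries' roles exchanged; the
    pair equals the lower/upper tails of Binomial(x+y, N2/(N1+N2)) at y, so
    the result is exactly exchange-symmetric.
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    return min(1.0, 2.0 * min(_upper_tail(x, y, n1, n2), _upper_tail(y, x, n2, n1)))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up adjusted q-values, in the input order.

    q(i) = min over j with p(j) >= p(i) of m * p(j) / rank(j), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class DEResult:
    gene_id: str
    x: int
    y: int
    n1: int
    n2: int
    tpm1: float
    tpm2: float
    log2_ratio: float
    p_value: float
    fdr: float = float("nan")
    significant: bool = False


def call_de_genes(
    matrix: ExpressionMatrix,
    lib1: str,
    lib2: str,
    fdr_max: float = 0.001,
    min_abs_log2: float = 1.0,
) -> list[DEResult]:
    """Test every gene detected in at least one of the two libraries.

    The log2 ratio is oriented lib2 over lib1 (treated/resistant over
    reference), computed on floored TPMs. Results are sorted by FDR
    ascending, then |log2 ratio| descending, then gene id.
    """
    if lib1 == lib2:
        raise ValueError("lib1 and lib2 must differ")
    for lib in (lib1, lib2):
        if lib not in matrix.libraries:
            raise ValueError(f"unknown library {lib!r}")
    n1 = matrix.library_totals[lib1]
    n2 = matrix.library_totals[lib2]
    results: list[DEResult] = []
    for gene in matrix.genes:
        x = int(matrix.counts.at[gene, lib1])
        y = int(matrix.counts.at[gene, lib2])
        if x == 0 and y == 0:
            continue
        tpm1 = float(matrix.tpm.at[gene, lib1])
        tpm2 = float(matrix.tpm.at[gene, lib2])
        results.append(
            DEResult(
                gene_id=gene,
                x=x,
                y=y,
                n1=n1,
                n2=n2,
                tpm1=tpm1,
                tpm2=tpm2,
                log2_ratio=math.log2(tpm2 / tpm1),
                p_value=ac_pvalue_two_sided(x, y, n1, n2),
            )
        )
    if results:
        q = benjamini_hochberg([r.p_value for r in results])
        for r, qi in zip(results, q):
            r.fdr = float(qi)
            r.significant = r.fdr <= fdr_max and abs(r.log2_ratio) >= min_abs_log2
    results.sort(key=lambda r: (r.fdr, -abs(r.log2_ratio), r.gene_id))
    return results
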