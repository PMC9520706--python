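"""Likelihood-ratio (G) tests of marginal and conditional independence.

The G statistic for two categorical variables ``A`` and ``B`` is

    G = 2 * sum_{a,b} N_ab * ln(N_ab / E_ab),    E_ab = N_.b * N_a. / N_..

and, conditioning on a joint configuration ``c`` of a set of categorical
variables ``C``, the per-stratum expected counts become
``E_abc = N_.bc * N_a.c / N_..c`` with the stratum G-values summed
(G is additive across strata).  Degrees of freedom follow the
``(Cat(A)-1)(Cat(B)-1) * prod_i Cat(C_i)`` convention, reduced for empty
rows/columns: within each stratum only rows and columns with a non-zero
margin are counted, so a degenerate stratum contributes nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "ContingencyTable",
    "GTestResult",
    "build_table",
    "g_statistic",
    "corrected_dof",
    "g_test",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Observed and expected counts of (A, B) within conditioning strata.

    ``counts`` and ``expected`` have shape ``(n_cat_a, n_cat_b, n_strata)``;
    when the conditioning set is empty there is a single stratum.  Expected
    counts are computed per stratum from the margins, so ``expected`` is zero
    exactly where a row or column margin of the stratum is zero.
    """

    counts: np.ndarray
    expected: np.ndarray

    def __post_init__(self) -> None:
        if self.counts.shape != self.expected.shape or self.counts.ndim != 3:
            raise ValueError("counts and expected must share a 3-d shape")

    @property
    def n_strata(self) -> int:
        return self.counts.shape[2]


@dataclass(frozen=True)
class GTestResult:
    """G statistic with its empty-cell-corrected degrees of freedom."""

    g: float
    dof: int
    p_value: float
    n_strata_used: int

    @property
    def dependent_at(self):  # convenience, used by the CLI report
        return lambda alpha: self.dof >= 1 and self.p_value < alpha


def _encode(v: np.ndarray) -> tuple[np.ndarray, int]:
    """Map an integer-coded categorical vector to 0..k-1 codes."""
    cats, codes = np.unique(np.asarray(v), return_inverse=True)
    return codes, len(cats)


def build_table(a, b, cond=()) -> ContingencyTable:
    """Cross-tabulate ``a`` vs ``b`` within each joint configuration of ``cond``.

    Parameters
    ----------
    a, b : array-like of int
        Categorical vectors of equal length.
    cond : sequence of array-like
        Conditioning vectors; empty sequence gives the marginal table.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    cond = [np.asarray(z) for z in cond]
    n = a.shape[0]
    if n == 0:
        raise ValueError("vectors must be non-empty")
    for v in [b, *cond]:
        if v.shape[0] != n:
            raise ValueError("all vectors must have the same length")

    ca_codes, ca = _encode(a)
    cb_codes, cb = _encode(b)
    if cond:
        # mixed-radix encoding of the joint conditioning configuration
        strat = np.zeros(n, dtype=np.int64)
        for z in cond:
            z_codes, kz = _encode(z)
            strat = strat * kz + z_codes
        # keep only configurations that actually occur
        _, strat = np.unique(strat, return_inverse=True)
        ns = int(strat.max()) + 1
    else:
        strat = np.zeros(n, dtype=np.int64)
        ns = 1

    flat = (ca_codes * cb + cb_codes) * ns + strat
    counts = np.bincount(flat, minlength=ca * cb * ns).reshape(ca, cb, ns)

    row = counts.sum(axis=1, keepdims=True).astype(float)   # N_a.c
    col = counts.sum(axis=0, keepdims=True).astype(float)   # N_.bc
    tot = counts.sum(axis=(0, 1), keepdims=True).astype(float)  # N_..c
    with np.errstate(invalid="ignore", divide="ignore"):
        expected = np.where(tot > 0, row * col / np.where(tot > 0, tot, 1.0), 0.0)
    return ContingencyTable(counts=counts, expected=expected)


def g_statistic(table: ContingencyTable) -> float:
    """G = 2 Σ N ln(N/E) over non-empty cells, summed across strata."""
    n = table.counts
    e = table.expected
    mask = n > 0
    # E = 0 with N > 0 is impossible: a zero margin forces N = 0
    assert np.all(e[mask] > 0), "observed count in a cell with zero expected"
    return float(2.0 * np.sum(n[mask] * np.log(n[mask] / e[mask])))


def corrected_dof(table: ContingencyTable) -> int:
    """Degrees of freedom with empty rows/columns removed per stratum.

    Each stratum contributes ``(r-1)(k-1)`` where r, k count the rows and
    columns of that stratum with a non-zero margin; the textbook
    ``(Cat(A)-1)(Cat(B)-1)·∏Cat(C_i)`` is recovered when nothing is empty.
    """
    n = table.counts
    rows = (n.sum(axis=1) > 0).sum(axis=0)  # per-stratum non-empty rows
    cols = (n.sum(axis=0) > 0).sum(axis=0)
    df = np.maximum(0, rows - 1) * np.maximum(0, cols - 1)
    return int(df.sum())


def g_test(a, b, cond=(), alpha: float = 0.01) -> tuple[GTestResult, bool]:
    """Test (conditional) independence of ``a`` and ``b``.

    Returns the :class:`GTestResult` and a verdict: ``True`` means
    "dependent" (p < alpha with at least one degree of freedom).  A table
    with zero corrected degrees of freedom carries no evidence of
    dependence, so the verdict is independent.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    table = build_table(a, b, cond)
    g = g_statistic(table)
    dof = corrected_dof(table)
    strata_used = int((table.counts.sum(axis=(0, 1)) > 0).sum())
    if dof == 0:
        res = GTestResult(g=g, dof=0, p_value=1.0, n_strata_used=strata_used)
        return res, False
    p = float(sps.chi2.sf(g, dof))
    res = GTestResult(g=g, dof=dof, p_value=p, n_strata_used=strata_used)
    return res, bool(p < alpha)
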