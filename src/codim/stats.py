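"""Shared statistical primitives for module discovery and characterization.

Every enrichment and overlap question in the pipeline reduces to one of a
small set of tests: an upper-tail hypergeometric overlap probability, a
one-sided Fisher exact test on a 2x2 table, Benjamini-Hochberg FDR
adjustment, Pearson correlation, or an empirical (permutation) p-value.
They are collected here so each downstream stage tests against one audited
implementation.

All enrichment tests are one-sided ("greater"): the pipeline only ever
interprets over-representation, never depletion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable",
    "PValueVector",
    "hypergeom_overlap_p",
    "fisher_exact_greater",
    "bh_fdr",
    "pearson_correlation",
    "empirical_p",
    "DomainError",
    "ConstantInputError",
]


class DomainError(ValueError):
    """Input outside the mathematical domain of a statistic."""


class ConstantInputError(DomainError):
    """Correlation requested for a constant vector; the caller decides the fallback."""


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 contingency table of drug (or gene) set membership.

    ``a`` counts items both in the query set and annotated, ``b`` in the set
    but not annotated, ``c`` annotated but outside the set, ``d`` neither.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in counts):
            raise DomainError(f"counts must be non-negative integers, got {counts}")
        if sum(counts) <= 0:
            raise DomainError("contingency table total must be positive")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class PValueVector:
    """Raw p-values with optional BH-adjusted q-values."""

    p: np.ndarray
    q: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.size and (np.nanmin(self.p) < 0 or np.nanmax(self.p) > 1):
            raise DomainError("p-values must lie in [0, 1]")
        if self.q is not None:
            self.q = np.asarray(self.q, dtype=float)


def hypergeom_overlap_p(overlap: int, size_a: int, size_b: int, universe: int) -> float:
    """Upper-tail P(X >= overlap) for X ~ Hypergeom(universe, size_a, size_b).

    The probability that two sets of sizes ``size_a`` and ``size_b``, drawn
    from a universe of ``universe`` items, share at least ``overlap`` items.
    """
    if universe <= 0:
        raise DomainError("universe must be positive")
    if not (0 <= size_a <= universe and 0 <= size_b <= universe):
        raise DomainError("set sizes must lie within the universe")
    lo = max(0, size_a + size_b - universe)
    hi = min(size_a, size_b)
    if not (lo <= overlap <= hi):
        raise DomainError(
            f"overlap {overlap} outside feasible range [{lo}, {hi}] "
            f"for sizes ({size_a}, {size_b}) in universe {universe}"
        )
    # sf(k-1) = P(X >= k); exact in scipy for these scales
    return float(_sps.hypergeom.sf(overlap - 1, universe, size_a, size_b))


def fisher_exact_greater(table: ContingencyTable) -> float:
    """One-sided ("greater") Fisher exact P for a 2x2 table.

    Identical to :func:`hypergeom_overlap_p` on the equivalent
    parametrization: overlap ``a``, set sizes ``a+b`` and ``a+c``,
    universe ``a+b+c+d``.
    """
    return hypergeom_overlap_p(
        table.a, table.a + table.b, table.a + table.c, table.total
    )


def bh_fdr(p) -> PValueVector:
    """Benjamini-Hochberg step-up FDR adjustment.

    Returns a :class:`PValueVector` whose ``q`` holds the adjusted values,
    clipped to 1, equivariant under permutation of the input order.
    """
    vec = p if isinstance(p, PValueVector) else PValueVector(np.asarray(p, dtype=float))
    if vec.p.size == 0:
        return PValueVector(vec.p.copy(), vec.p.copy())
    q = multipletests(vec.p, method="fdr_bh")[1]
    return PValueVector(vec.p.copy(), q)


def pearson_correlation(x, y) -> float:
    """Standard Pearson r; raises :class:`ConstantInputError` on flat input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise DomainError("x and y must be equal-length 1-d vectors of length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation undefined for a constant vector")
    xc = x - x.mean()
    yc = y - y.mean()
    return float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))


def empirical_p(observed: float, null_samples) -> float:
    """Permutation p-value with the add-one rule: (1 + #{null >= obs}) / (1 + n).

    The add-one convention guarantees P > 0 and makes the minimum attainable
    value exactly 1/(n+1), matching the reporting style "P < 0.001 at 1000
    permutations".
    """
    null = np.asarray(null_samples, dtype=float)
    if null.size == 0:
        raise DomainError("null sample set must be non-empty")
    return float((1 + np.count_nonzero(null >= observed)) / (1 + null.size))
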