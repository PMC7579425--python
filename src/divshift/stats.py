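"""The diversity-shift statistic.

Given a taxon x location-class proportion profile, the procedure is:

1. order the location classes by hierarchical clustering of their columns
   (or accept a forced ordering),
2. regress each taxon's proportion on the ordered class ranks by ordinary
   least squares -- with a single pooled value per class there are only as
   many points as classes, so no per-taxon p-value is meaningful, but the
   slope and in particular its sign are well defined,
3. test whether negative slopes are enriched among taxa with an exact
   one-sided binomial test under a fair-coin null.

The binomial tail is computed with exact integer binomial coefficients and
divided once at the end, so the p-value is correct to full float precision
for any number of taxa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage, optimal_leaf_ordering
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "ClassOrdering",
    "SignEnrichment",
    "DivShiftReport",
    "order_classes",
    "fit_slopes",
    "sign_enrichment",
    "binomial_tail",
    "run_divshift",
]

SIGN_TOL = 1e-12


@dataclass
class ClassOrdering:
    """An ordering of location classes with its provenance.

    ``provenance`` is ``"clustered"`` when the order was read off an
    agglomerative merge tree and ``"forced"`` when supplied by the caller.
    ``linkage_matrix``/``labels`` retain the tree (when clustered) so the
    dendrogram can be exported as Newick.
    """

    order: list[str]
    provenance: str
    linkage_matrix: np.ndarray | None = None
    labels: list[str] = field(default_factory=list)

    def to_newick(self) -> str:
        """Serialize the dendrogram as a Newick string with branch lengths."""
        if self.linkage_matrix is None:
            raise ValueError("no dendrogram available for a forced ordering")
        return _linkage_to_newick(self.linkage_matrix, self.labels)

    def reversed(self) -> "ClassOrdering":
        return ClassOrdering(
            order=list(reversed(self.order)),
            provenance=self.provenance,
            linkage_matrix=self.linkage_matrix,
            labels=self.labels,
        )


@dataclass
class SignEnrichment:
    """Result of the negative-slope sign test.

    ``k`` negative slopes out of ``n`` informative taxa (``n_zero`` exact-zero
    slopes are excluded from both), with the exact binomial tail
    ``P(X >= k), X ~ Binomial(n, 1/2)`` for the default one-sided
    ``"greater"`` alternative.
    """

    k: int
    n: int
    n_zero: int
    p_value: float
    alternative: str = "greater"

    def to_dict(self) -> dict:
        return {
            "k_negative": self.k,
            "n_informative": self.n,
            "n_zero_excluded": self.n_zero,
            "p_value": self.p_value,
            "alternative": self.alternative,
        }


@dataclass
class DivShiftReport:
    ordering: ClassOrdering
    slopes: pd.DataFrame
    enrichment: SignEnrichment
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "ordering": self.ordering.order,
            "ordering_provenance": self.ordering.provenance,
            "enrichment": self.enrichment.to_dict(),
            "params": self.params,
        }


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    n = len(labels)

    def height(i: int) -> float:
        return 0.0 if i < n else float(Z[i - n, 2])

    def rec(i: int) -> str:
        if i < n:
            return labels[i]
        a, b = int(Z[i - n, 0]), int(Z[i - n, 1])
        h = height(i)
        return f"({rec(a)}:{h - height(a):.6g},{rec(b)}:{h - height(b):.6g})"

    return rec(2 * n - 2) + ";"


def _tree_orders(Z: np.ndarray, n: int) -> list[tuple[int, ...]]:
    """All leaf orders consistent with the merge tree (every node may flip)."""

    def rec(i: int) -> list[tuple[int, ...]]:
        if i < n:
            return [(i,)]
        a, b = int(Z[i - n, 0]), int(Z[i - n, 1])
        out = []
        for left in rec(a):
            for right in rec(b):
                out.append(left + right)
                out.append(right + left)
        return out

    return rec(2 * n - 2)


def order_classes(
    profile: pd.DataFrame, metric: str = "euclidean", method: str = "average"
) -> ClassOrdering:
    """Order location classes by agglomerative clustering of profile columns.

    The leaf order is read from the merge tree: among all leaf orders the
    tree admits, those that start with the earliest-merged (tightest) pair
    are kept -- so each later-joining class is appended after the classes it
    is most similar to -- and of these the order minimizing the total
    distance between adjacent leaves is chosen (ties broken
    lexicographically).  For a profile whose column distances satisfy
    d(L,C) < d({L,C},H) < d({L,C,H},S) this yields the order (L, C, H, S).
    """
    cols = list(profile.columns)
    n = len(cols)
    if n < 2:
        raise ValueError("need at least 2 location classes to order")
    if n == 2:
        return ClassOrdering(order=cols, provenance="clustered", labels=cols)

    X = profile.T.to_numpy(dtype=float)
    D = pdist(X, metric=metric)
    Z = linkage(D, method=method)
    if np.ptp(X, axis=0).max() == 0:
        warnings.warn(
            "all class columns are identical; ordering is arbitrary (input order kept)",
            stacklevel=2,
        )
        return ClassOrdering(order=cols, provenance="clustered",
                             linkage_matrix=Z, labels=cols)

    if n <= 10:
        Dsq = squareform(D)
        first_pair = {int(Z[0, 0]), int(Z[0, 1])}
        candidates = [
            o for o in _tree_orders(Z, n) if {o[0], o[1]} == first_pair
        ]

        def cost(o: tuple[int, ...]) -> float:
            return float(sum(Dsq[o[i], o[i + 1]] for i in range(n - 1)))

        order_idx = list(min(candidates, key=lambda o: (cost(o), o)))
    else:  # large class sets: fall back to optimal leaf ordering
        Zopt = optimal_leaf_ordering(Z, D)
        order_idx = list(leaves_list(Zopt))
        first_pair = {int(Z[0, 0]), int(Z[0, 1])}
        if order_idx[0] not in first_pair and order_idx[-1] in first_pair:
            order_idx = order_idx[::-1]

    return ClassOrdering(
        order=[cols[i] for i in order_idx],
        provenance="clustered",
        linkage_matrix=Z,
        labels=cols,
    )


def fit_slopes(
    profile: pd.DataFrame, ordering: ClassOrdering, tol: float = SIGN_TOL
) -> pd.DataFrame:
    """OLS slope of each taxon's proportion against ordered class rank.

    Classes are coded x = 0, 1, ..., m-1 in ordering order; the slope is
    cov(x, y) / var(x).  The sign (``neg``/``zero``/``pos``) is assigned with
    tolerance ``tol`` and is invariant to any increasing affine recoding
    of x.
    """
    if set(ordering.order) != set(profile.columns):
        raise ValueError("ordering does not cover the profile's classes")
    m = len(ordering.order)
    if m < 2:
        raise ValueError("need at least 2 classes to fit slopes")
    Y = profile[ordering.order].to_numpy(dtype=float)
    x = np.arange(m, dtype=float)
    xc = x - x.mean()
    slopes = (Y - Y.mean(axis=1, keepdims=True)) @ xc / (xc @ xc)
    sign = np.where(slopes < -tol, "neg", np.where(slopes > tol, "pos", "zero"))
    return pd.DataFrame(
        {"slope": slopes, "sign": sign}, index=profile.index.copy()
    )


def binomial_tail(k: int, n: int) -> float:
    """Exact upper tail P(X >= k) for X ~ Binomial(n, 1/2).

    Summed with integer binomial coefficients and divided once, so e.g.
    k=22, n=25 gives exactly 2626 / 2**25.
    """
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    return float(Fraction(sum(comb(n, i) for i in range(k, n + 1)), 2**n))


def sign_enrichment(
    slopes: pd.DataFrame, alternative: str = "greater"
) -> SignEnrichment:
    """Exact binomial test for enrichment of negative slopes.

    Zero slopes carry no directional information and are excluded from both
    the numerator and the denominator; their count is reported.  The default
    one-sided alternative tests whether negative signs are more frequent
    than the fair-coin null expects; ``"two-sided"`` doubles the smaller
    tail (capped at 1).
    """
    if alternative not in ("greater", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    signs = slopes["sign"] if isinstance(slopes, pd.DataFrame) else pd.Series(slopes)
    k = int((signs == "neg").sum())
    n_zero = int((signs == "zero").sum())
    n = int((signs != "zero").sum())
    if n == 0:
        raise ValueError("no informative slopes")
    upper = binomial_tail(k, n)
    if alternative == "greater":
        p = upper
    else:
        lower = float(Fraction(sum(comb(n, i) for i in range(0, k + 1)), 2**n))
        p = min(1.0, 2.0 * min(upper, lower))
    return SignEnrichment(k=k, n=n, n_zero=n_zero, p_value=p, alternative=alternative)


def run_divshift(
    profile: pd.DataFrame,
    forced_order: list[str] | None = None,
    metric: str = "euclidean",
    method: str = "average",
    alternative: str = "greater",
) -> DivShiftReport:
    """Full shift analysis: ordering, per-taxon slopes, sign enrichment."""
    if forced_order is not None:
        if sorted(forced_order) != sorted(profile.columns):
            raise ValueError(
                f"forced order {forced_order} is not a permutation of "
                f"classes {list(profile.columns)}"
            )
        ordering = ClassOrdering(order=list(forced_order), provenance="forced")
    else:
        ordering = order_classes(profile, metric=metric, method=method)
    slopes = fit_slopes(profile, ordering)
    enrichment = sign_enrichment(slopes, alternative=alternative)
    return DivShiftReport(
        ordering=ordering,
        slopes=slopes,
        enrichment=enrichment,
        params={"metric": metric, "linkage": method, "alternative": alternative},
    )
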