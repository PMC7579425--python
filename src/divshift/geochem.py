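"""Geochemistry arm: PCA, PAM clustering, Dunn tests and NMDS vector fitting.

Porewater/sediment chemistry enters the pipeline twice.  First it is
summarized on its own: a unit-variance (correlation-matrix) PCA of the
sample x feature table, with the scores clustered by Partitioning Around
Medoids (cluster count chosen by mean silhouette width), and per-feature
rank-based Dunn pairwise comparisons with Benjamini-Hochberg adjustment.
Second it is related to the community: a two-dimensional non-metric
multidimensional scaling (NMDS) of Bray-Curtis community dissimilarities,
onto which each chemistry feature is fitted as a least-squares vector with
a permutation p-value (vegan-style "envfit").
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kruskal, norm, rankdata
from sklearn.manifold import MDS
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PCAResult",
    "pca_unit_variance",
    "PAMResult",
    "pam",
    "pam_silhouette",
    "dunn_bh",
    "NMDSResult",
    "nmds_envfit",
]


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: pd.DataFrame              # sample x component
    loadings: pd.DataFrame            # feature x component
    variance_fractions: pd.Series     # component -> fraction of total variance

    def reconstruct(self) -> pd.DataFrame:
        """Scores @ loadings.T; equals the centered/scaled table."""
        return self.scores @ self.loadings.T


def pca_unit_variance(table: pd.DataFrame) -> PCAResult:
    """PCA of a sample x feature table scaled to unit variance.

    Features are centered and divided by their (ddof=1) standard deviation,
    so the decomposition is of the correlation structure.  The sign of each
    component is fixed so its largest-magnitude loading is positive.
    """
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples and 2 features")
    X = table.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    zero = sd <= 0
    if zero.any():
        raise ValueError(
            f"zero-variance features: {table.columns[zero].tolist()}"
        )
    Z = (X - X.mean(axis=0)) / sd
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    # deterministic orientation: largest |loading| positive per component
    for j in range(Vt.shape[0]):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    comps = [f"PC{i + 1}" for i in range(len(s))]
    scores = pd.DataFrame(U * s, index=table.index, columns=comps)
    loadings = pd.DataFrame(Vt.T, index=table.columns, columns=comps)
    frac = pd.Series(s**2 / (s**2).sum(), index=comps, name="variance_fraction")
    return PCAResult(scores=scores, loadings=loadings, variance_fractions=frac)


# --------------------------------------------------------------------------
# PAM / silhouette
# --------------------------------------------------------------------------

@dataclass
class PAMResult:
    labels: pd.Series                 # sample -> cluster id (0-based)
    k: int
    medoids: list
    silhouettes: dict[int, float]     # k -> mean silhouette width
    objective: float                  # total distance to assigned medoids


def _pam_once(D: np.ndarray, k: int) -> tuple[np.ndarray, float]:
    """Classic PAM: greedy BUILD then repeated best-improvement SWAP.

    Both phases are deterministic, so results depend only on the
    dissimilarity matrix.  Returns (medoid indices, objective).
    """
    n = D.shape[0]
    # BUILD: first medoid minimizes total distance; then greedy additions
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        dist_to_near = D[:, medoids].min(axis=1)
        gains = np.array([
            np.maximum(dist_to_near - D[:, j], 0.0).sum() if j not in medoids else -1.0
            for j in range(n)
        ])
        medoids.append(int(np.argmax(gains)))
    medoids = sorted(medoids)

    def cost(meds: list[int]) -> float:
        return float(D[:, meds].min(axis=1).sum())

    best_cost = cost(medoids)
    improved = True
    while improved:
        improved = False
        best_swap = None
        for m in list(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = sorted(set(medoids) - {m} | {h})
                c = cost(trial)
                if c < best_cost - 1e-12:
                    best_cost, best_swap = c, trial
        if best_swap is not None:
            medoids, improved = best_swap, True
    return np.asarray(medoids), best_cost


def pam(D: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, float]:
    """PAM at fixed k on a square dissimilarity matrix.

    Returns (labels, medoid indices, objective).
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("D must be a square dissimilarity matrix")
    if not 1 <= k <= D.shape[0]:
        raise ValueError("k must be in [1, n]")
    medoids, obj = _pam_once(D, k)
    labels = np.argmin(D[:, medoids], axis=1)
    return labels, medoids, obj


def pam_silhouette(
    scores: pd.DataFrame | np.ndarray,
    k_range: range | None = None,
    metric: str = "euclidean",
    seed: int = 0,
) -> PAMResult:
    """PAM with cluster count chosen by maximum mean silhouette width.

    ``k_range`` defaults to 2..n-1.  Ties in silhouette width are broken
    toward the smaller k; duplicate points degenerate the silhouette and
    trigger a warning.  The ``seed`` is accepted for interface stability but
    the deterministic BUILD/SWAP algorithm does not use randomness.
    """
    X = scores.to_numpy(dtype=float) if isinstance(scores, pd.DataFrame) else np.asarray(scores, dtype=float)
    index = scores.index if isinstance(scores, pd.DataFrame) else pd.RangeIndex(len(X))
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points to choose a cluster count")
    D = squareform(pdist(X, metric=metric))
    if (pdist(X, metric=metric) == 0).any():
        warnings.warn("duplicate points present; silhouettes may degenerate",
                      stacklevel=2)
    if k_range is None:
        k_range = range(2, n)
    best: PAMResult | None = None
    sils: dict[int, float] = {}
    for k in k_range:
        if not 2 <= k <= n - 1:
            continue
        labels, medoids, obj = pam(D, k)
        if len(np.unique(labels)) < 2:
            continue
        sil = float(silhouette_score(D, labels, metric="precomputed"))
        sils[k] = sil
        if best is None or sil > best.silhouettes[best.k] + 1e-12:
            best = PAMResult(
                labels=pd.Series(labels, index=index, name="cluster"),
                k=k,
                medoids=[index[m] for m in medoids],
                silhouettes=sils,
                objective=obj,
            )
    if best is None:
        raise ValueError("no valid clustering found in k_range")
    best.silhouettes = sils
    return best


# --------------------------------------------------------------------------
# Dunn post-hoc comparisons
# --------------------------------------------------------------------------

def dunn_bh(
    values: pd.Series | np.ndarray,
    groups: pd.Series | np.ndarray,
    alpha: float = 0.025,
) -> pd.DataFrame:
    """Rank-based Dunn pairwise z tests with BH adjustment.

    The pooled-rank z statistic uses the tie-corrected variance
    ``(N(N+1)/12 - sum(t^3 - t)/(12(N-1))) * (1/n_i + 1/n_j)``.  Raw
    two-sided normal p-values are step-up adjusted (Benjamini-Hochberg) and
    flagged at ``alpha``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    names = pd.unique(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    sizes = {g: int((groups == g).sum()) for g in names}
    small = [g for g, sz in sizes.items() if sz < 2]
    if small:
        raise ValueError(f"groups with fewer than 2 observations: {small}")
    N = len(values)
    ranks = rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (N - 1)))
    var_factor = N * (N + 1) / 12.0 - tie_term
    mean_rank = {g: ranks[groups == g].mean() for g in names}
    rows = []
    for g1, g2 in itertools.combinations(names, 2):
        se = np.sqrt(var_factor * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = 0.0 if se == 0 else (mean_rank[g1] - mean_rank[g2]) / se
        p = 2.0 * norm.sf(abs(z))
        rows.append({"group1": g1, "group2": g2, "z": z, "p_raw": min(1.0, p)})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p_raw"], method="fdr_bh")[1]
    out["significant"] = out["p_adj"] < alpha
    try:
        out.attrs["kruskal_p"] = float(
            kruskal(*[values[groups == g] for g in names]).pvalue
        )
    except ValueError:  # all values identical
        out.attrs["kruskal_p"] = 1.0
    return out


# --------------------------------------------------------------------------
# NMDS + envfit
# --------------------------------------------------------------------------

@dataclass
class NMDSResult:
    coordinates: pd.DataFrame         # sample x (NMDS1, NMDS2)
    stress: float
    converged: bool
    fits: pd.DataFrame                # feature: direction cosines, r2, p
    n_perm: int = 0
    params: dict = field(default_factory=dict)


def _bray_curtis(community: pd.DataFrame) -> np.ndarray:
    X = community.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("community abundances must be non-negative")
    return pdist(X, metric="braycurtis")


def _vector_fit(coords: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, float]:
    vc = v - v.mean()
    A = coords - coords.mean(axis=0)
    beta, *_ = np.linalg.lstsq(A, vc, rcond=None)
    ss_tot = float(vc @ vc)
    resid = vc - A @ beta
    r2 = 1.0 - float(resid @ resid) / ss_tot
    norm_b = np.linalg.norm(beta)
    cosines = beta / norm_b if norm_b > 0 else beta
    return cosines, max(0.0, r2)


def nmds_envfit(
    community: pd.DataFrame,
    env: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    n_restarts: int = 20,
    max_iter: int = 300,
) -> NMDSResult:
    """2-D NMDS of Bray-Curtis dissimilarities with environmental vectors.

    ``community`` is a sample x taxon abundance table (genome- or
    phylum-level both work); ``env`` a sample x feature chemistry table on
    the same samples.  The stress minimization is restarted ``n_restarts``
    times from random configurations and the lowest-stress solution kept;
    non-convergence is reported through ``converged``, never silently.  Each
    feature's permutation p-value uses the add-one estimator
    ``(1 + #{permuted r2 >= observed}) / (1 + n_perm)`` and therefore never
    equals 0.
    """
    if not community.index.equals(env.index):
        if sorted(community.index) != sorted(env.index):
            raise ValueError("community and env tables have different samples")
        env = env.loc[community.index]
    n = len(community)
    if n < 3:
        raise ValueError("need at least 3 samples for an ordination")
    sd = env.to_numpy(dtype=float).std(axis=0, ddof=1)
    if (sd <= 0).any():
        raise ValueError(
            f"zero-variance env features: {env.columns[(sd <= 0)].tolist()}"
        )
    rng = np.random.default_rng(seed)
    D = squareform(_bray_curtis(community))

    import inspect

    mds_params = inspect.signature(MDS).parameters
    if "metric_mds" in mds_params:  # sklearn >= 1.9 naming
        nonmetric_kw = {"metric": "precomputed", "metric_mds": False}
    else:
        nonmetric_kw = {"metric": False, "dissimilarity": "precomputed"}
    if "init" in mds_params:
        nonmetric_kw["init"] = "random"  # random restarts are the point here

    best_coords, best_stress, converged = None, np.inf, False
    for _ in range(n_restarts):
        mds = MDS(
            n_components=2,
            n_init=1,
            max_iter=max_iter,
            random_state=int(rng.integers(0, 2**31 - 1)),
            normalized_stress=True,
            **nonmetric_kw,
        )
        coords = mds.fit_transform(D)
        if mds.stress_ < best_stress:
            best_stress = float(mds.stress_)
            best_coords = coords
            converged = mds.n_iter_ < max_iter
    if best_stress > 0.3:
        warnings.warn(
            f"NMDS stress {best_stress:.3f} is high; ordination may be unreliable",
            stacklevel=2,
        )
    coords = pd.DataFrame(best_coords, index=community.index,
                          columns=["NMDS1", "NMDS2"])

    rows = []
    A = coords.to_numpy()
    for feat in env.columns:
        v = env[feat].to_numpy(dtype=float)
        cosines, r2 = _vector_fit(A, v)
        exceed = 0
        for _ in range(n_perm):
            _, r2p = _vector_fit(A, rng.permutation(v))
            if r2p >= r2:
                exceed += 1
        p = (1 + exceed) / (1 + n_perm)
        rows.append(
            {"feature": feat, "NMDS1": cosines[0], "NMDS2": cosines[1],
             "r2": r2, "p_value": p}
        )
    fits = pd.DataFrame(rows).set_index("feature")
    return NMDSResult(
        coordinates=coords,
        stress=best_stress,
        converged=converged,
        fits=fits,
        n_perm=n_perm,
        params={"n_restarts": n_restarts, "dissimilarity": "braycurtis"},
    )
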