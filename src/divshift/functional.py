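"""Functional-potential arm of the pipeline.

From genome -> function annotations and pathway -> enzyme definitions this
module (i) selects, per site, the genomes abundant enough to contribute to
functional summaries, (ii) infers a most-parsimonious pathway set per genome
(minimum set cover of its observed enzymes), (iii) builds a
(taxon, pathway) x location-class proportion profile -- splitting
Proteobacteria by class by default -- that feeds the same slope /
sign-enrichment machinery as the taxonomic arm, and (iv) compares major
nutrient-cycling processes (carbon, nitrogen, sulfur) between the low- and
high-runoff transects with exact Fisher tests and a hierarchically
clustered site dendrogram supported by multiscale (approximately unbiased)
bootstrap.

Abundance inclusion cutoff
--------------------------
The inclusion rule keeps genome g at site s when
``-log10(a_gs / max_s' a_gs') <= cutoff`` ("max_scaled", the default): the
genome must be within ``10**cutoff``-fold of its own best site.  A "raw"
transform (``-log10(a_gs) <= cutoff``) is also available; with hundreds of
genomes it admits only genomes exceeding ``10**-cutoff`` of a sample and is
therefore far stricter.  The transform used is recorded by callers that
serialize reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from scipy.stats import hypergeom, norm

from .community import AbundanceTable, _taxon_labels, validate_design
from .stats import DivShiftReport, run_divshift

__all__ = [
    "PathwayCalls",
    "include_genomes_per_site",
    "minpath_infer",
    "call_pathways",
    "build_pathway_profile",
    "functional_divshift",
    "fisher_exact_2x2",
    "compare_nutrient_processes",
    "NutrientReport",
]

#: Largest number of candidate pathways for which set cover is solved exactly.
EXACT_COVER_LIMIT = 20

#: Default multiscale-bootstrap scales (relative resample sizes).
AU_SCALES = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2, 1.3, 1.4)


def include_genomes_per_site(
    props: AbundanceTable, cutoff: float = 0.25, transform: str = "max_scaled"
) -> dict[str, set[str]]:
    """Select the most abundant genomes at each site.

    See the module docstring for the two transforms.  Genomes with zero
    abundance everywhere are excluded with a warning; a zero abundance at a
    single site is never included (its -log10 is infinite).
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    if transform not in ("max_scaled", "raw"):
        raise ValueError(f"unknown transform {transform!r}")
    if not props.is_proportions:
        raise ValueError("inclusion cutoff requires a proportion-mode table")
    data = props.data
    values = data.to_numpy(dtype=float)
    row_max = values.max(axis=1)
    dead = row_max <= 0
    if dead.any():
        warnings.warn(
            f"genomes with zero abundance everywhere excluded: "
            f"{data.index[dead].tolist()}",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        if transform == "max_scaled":
            score = -np.log10(values / row_max[:, None])
        else:
            score = -np.log10(values)
    included = (score <= cutoff) & (values > 0) & ~dead[:, None]
    return {
        site: set(data.index[included[:, j]])
        for j, site in enumerate(data.columns)
    }


@dataclass(frozen=True)
class PathwayCalls:
    """A parsimonious pathway assignment for one enzyme set.

    ``single_hit`` flags pathways supported by only one observed enzyme;
    parsimony keeps them when nothing else covers that enzyme, but they are
    weak evidence and callers may drop them (multi-gene support only).
    ``unmapped`` holds observed enzymes absent from every definition.
    """

    pathways: frozenset[str]
    single_hit: frozenset[str]
    unmapped: frozenset[str]

    @property
    def multi_hit(self) -> frozenset[str]:
        return self.pathways - self.single_hit


def _greedy_cover(
    uncovered: set[str], cands: dict[str, frozenset[str]]
) -> list[str]:
    chosen: list[str] = []
    uncovered = set(uncovered)
    while uncovered:
        # max new coverage, ties to the lexicographically smallest pathway id
        best = min(cands, key=lambda p: (-len(cands[p] & uncovered), p))
        gain = cands[best] & uncovered
        if not gain:  # pragma: no cover - uncoverable enzymes filtered earlier
            break
        chosen.append(best)
        uncovered -= gain
    return chosen


def _exact_cover(
    enzymes: frozenset[str], cands: dict[str, frozenset[str]]
) -> list[str]:
    """Branch-and-bound minimum set cover; deterministic tie-breaking."""
    upper = _greedy_cover(set(enzymes), cands)
    best: list[str] = sorted(upper)
    by_enzyme: dict[str, list[str]] = {
        e: sorted((p for p in cands if e in cands[p])) for e in enzymes
    }
    max_size = max(len(s) for s in cands.values())

    def dfs(uncovered: frozenset[str], chosen: tuple[str, ...]) -> None:
        nonlocal best
        if not uncovered:
            if len(chosen) < len(best) or (
                len(chosen) == len(best) and sorted(chosen) < best
            ):
                best = sorted(chosen)
            return
        # lower bound: each pathway covers at most max_size enzymes
        if len(chosen) + -(-len(uncovered) // max_size) > len(best):
            return
        if len(chosen) + 1 > len(best):
            return
        # branch on the enzyme with fewest candidate pathways
        e = min(uncovered, key=lambda x: (len(by_enzyme[x]), x))
        for p in by_enzyme[e]:
            if p in chosen:
                continue
            dfs(uncovered - cands[p], chosen + (p,))

    dfs(enzymes, ())
    return best


def minpath_infer(
    observed_enzymes: Iterable[str],
    definitions: Mapping[str, Iterable[str]],
    exact_limit: int = EXACT_COVER_LIMIT,
) -> PathwayCalls:
    """Minimum-cardinality pathway set covering the observed enzymes.

    Solved exactly (branch and bound) when at most ``exact_limit`` pathways
    intersect the observed enzymes, greedily otherwise.  Among equally small
    exact covers the lexicographically smallest pathway-id set is returned.
    """
    if not definitions:
        raise ValueError("pathway definitions are empty")
    empty = [p for p, es in definitions.items() if not set(es)]
    if empty:
        raise ValueError(f"pathways with empty definitions: {sorted(empty)}")
    observed = frozenset(observed_enzymes)
    if not observed:
        return PathwayCalls(frozenset(), frozenset(), frozenset())
    cands = {
        p: frozenset(es) & observed
        for p, es in definitions.items()
        if frozenset(es) & observed
    }
    coverable = frozenset().union(*cands.values()) if cands else frozenset()
    unmapped = observed - coverable
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} observed enzymes not in any pathway definition",
            stacklevel=2,
        )
    if not cands:
        return PathwayCalls(frozenset(), frozenset(), frozenset(unmapped))
    if len(cands) <= exact_limit:
        chosen = _exact_cover(coverable, cands)
    else:
        chosen = _greedy_cover(set(coverable), cands)
    single = frozenset(p for p in chosen if len(cands[p]) == 1)
    return PathwayCalls(frozenset(chosen), single, frozenset(unmapped))


def call_pathways(
    annotations: Mapping[str, Iterable[str]],
    definitions: Mapping[str, Iterable[str]],
    require_multi_hit: bool = True,
) -> dict[str, set[str]]:
    """Per-genome parsimonious pathway calls.

    With ``require_multi_hit`` only pathways supported by at least two
    observed enzymes are reported.
    """
    calls = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-genome unmapped warnings are noisy
        for g, enzymes in annotations.items():
            res = minpath_infer(enzymes, definitions)
            calls[g] = set(res.multi_hit if require_multi_hit else res.pathways)
    return calls


def build_pathway_profile(
    included_by_site: Mapping[str, Iterable[str]],
    features: Mapping[str, Iterable[str]],
    taxonomy: pd.DataFrame | pd.Series,
    design: Mapping[str, str] | pd.Series,
    split_proteobacteria_by_class: bool = True,
) -> pd.DataFrame:
    """(taxon, feature) x location-class presence proportions.

    ``features`` maps each genome to the pathway (or function) ids counted
    for it -- set semantics, so duplicated annotations cannot inflate a
    genome's contribution.  A genome counts toward a class when it is
    included at any site of that class; each column is normalized to 1.
    """
    design = validate_design(design, included_by_site.keys())
    classes = list(dict.fromkeys(design[s] for s in included_by_site))
    class_genomes: dict[str, set[str]] = {c: set() for c in classes}
    for site, genomes in included_by_site.items():
        class_genomes[design[site]].update(genomes)
    empty = [c for c, gs in class_genomes.items() if not gs]
    if empty:
        raise ValueError(f"no genomes included for location classes: {empty}")

    all_genomes = sorted(set().union(*class_genomes.values()))
    labels = _taxon_labels(taxonomy, all_genomes, split_proteobacteria_by_class)

    counts: dict[tuple[str, str], dict[str, int]] = {}
    for cls, genomes in class_genomes.items():
        for g in genomes:
            for feat in set(features.get(g, ())):
                row = counts.setdefault((labels[g], feat), dict.fromkeys(classes, 0))
                row[cls] += 1
    if not counts:
        raise ValueError("no features observed among included genomes")
    profile = pd.DataFrame.from_dict(counts, orient="index").fillna(0.0)
    profile = profile[classes]
    profile.index = pd.MultiIndex.from_tuples(profile.index, names=["taxon", "feature"])
    profile = profile.sort_index()
    sums = profile.sum(axis=0)
    if (sums <= 0).any():
        raise ValueError(
            f"no feature presences in classes: {sums.index[sums <= 0].tolist()}"
        )
    return profile.div(sums, axis=1)


def functional_divshift(
    pathway_profile: pd.DataFrame,
    forced_order: list[str] | None = None,
    collapse_to_taxon: bool = False,
    **kwargs,
) -> DivShiftReport:
    """Slope/sign-enrichment analysis of a pathway profile.

    With ``collapse_to_taxon`` the (taxon, feature) rows are summed within
    taxon first, regressing one pooled functional proportion per taxon.
    """
    profile = pathway_profile
    if collapse_to_taxon and isinstance(profile.index, pd.MultiIndex):
        profile = profile.groupby(level="taxon").sum()
    return run_divshift(profile, forced_order=forced_order, **kwargs)


def fisher_exact_2x2(table: np.ndarray | list[list[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table, minimum-likelihood rule.

    All tables with the observed margins whose hypergeometric probability
    does not exceed the observed table's are summed.  A small relative
    tolerance absorbs floating-point ties, matching exact rational
    enumeration.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative integers")
    a = t[0, 0]
    n = int(t.sum())
    if n == 0:
        return 1.0
    r1 = int(t[0].sum())
    c1 = int(t[:, 0].sum())
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[support == a][0]
    return float(min(1.0, pmf[pmf <= p_obs * (1.0 + 1e-9)].sum()))


def _process_counts(
    presence: np.ndarray, proc_onehot: np.ndarray, col_idx: np.ndarray | None = None
) -> np.ndarray:
    if col_idx is None:
        return presence @ proc_onehot
    return presence[:, col_idx] @ proc_onehot[col_idx]


def _au_from_curve(
    scales: np.ndarray, bp: np.ndarray, n_boot: int
) -> tuple[float, float]:
    """Approximately unbiased support from a multiscale bootstrap curve.

    Fits the normal-quantile model z(r) = d*sqrt(r) + c/sqrt(r) to
    z_r = qnorm(1 - BP_r) by weighted least squares (weights from the
    binomial variance of each BP_r), and returns (AU, fitted BP at r=1):
    AU = 1 - Phi(d - c), BP(1) = 1 - Phi(d + c).

    A flat curve (identical BP at every scale, e.g. saturated support)
    carries no curvature information, so the model is skipped and AU is the
    observed BP itself.
    """
    one = int(np.argmin(np.abs(scales - 1.0)))
    if np.ptp(bp) < 1e-12:
        return float(bp[one]), float(bp[one])
    eps = 1.0 / (2.0 * n_boot)
    bp = np.clip(bp, eps, 1.0 - eps)
    z = norm.ppf(1.0 - bp)
    X = np.column_stack([np.sqrt(scales), 1.0 / np.sqrt(scales)])
    w = n_boot * norm.pdf(z) ** 2 / (bp * (1.0 - bp))
    WX = X * w[:, None]
    beta, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ z, rcond=None)
    d, c = beta
    return float(1.0 - norm.cdf(d - c)), float(1.0 - norm.cdf(d + c))


def _clades(Z: np.ndarray, labels: list[str]) -> set[frozenset[str]]:
    n = len(labels)
    members: dict[int, frozenset[str]] = {i: frozenset([labels[i]]) for i in range(n)}
    out = set()
    for i, row in enumerate(Z):
        merged = members[int(row[0])] | members[int(row[1])]
        members[n + i] = merged
        if 1 < len(merged) < n:
            out.add(merged)
    return out


@dataclass
class NutrientReport:
    """Transect comparison of nutrient-cycling processes."""

    fisher: pd.DataFrame          # per process: 2x2 counts and exact p
    clades: pd.DataFrame          # per site clade: BP and AU support
    linkage_matrix: np.ndarray = field(repr=False, default=None)
    site_order: list[str] = field(default_factory=list)
    skipped_processes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "fisher": self.fisher.reset_index().to_dict(orient="records"),
            "clades": self.clades.to_dict(orient="records"),
            "skipped_processes": self.skipped_processes,
        }


def compare_nutrient_processes(
    presence: pd.DataFrame,
    process_map: Mapping[str, str] | pd.Series,
    design: Mapping[str, str] | pd.Series,
    n_boot: int = 1000,
    scales: Iterable[float] = AU_SCALES,
    seed: int = 0,
    method: str = "average",
    metric: str = "euclidean",
) -> NutrientReport:
    """Compare C/N/S-cycle process repertoires between transects.

    Parameters
    ----------
    presence
        Site x function 0/1 table of function presence (any genome at the
        site carrying the function).
    process_map
        function id -> process label (e.g. ``carbon_oxidation``); processes
        mapped to no observed function are skipped with a warning.
    design
        site -> location class; the Fisher contrasts pool L sites against
        H sites.

    Returns a per-process Fisher exact report (presence/absence x L/H) and
    site-dendrogram supports: ordinary bootstrap probability (BP, at scale 1)
    and approximately unbiased (AU) support from the multiscale curve.
    """
    design = validate_design(design, presence.index)
    process_map = pd.Series(dict(process_map) if not isinstance(process_map, pd.Series) else process_map)
    unmapped = sorted(set(presence.columns) - set(process_map.index))
    if unmapped:
        raise ValueError(f"functions missing from the process map: {unmapped}")
    rng = np.random.default_rng(seed)

    sites = list(presence.index)
    funcs = list(presence.columns)
    P = presence.to_numpy(dtype=float)
    procs = sorted(process_map[funcs].unique())
    skipped = sorted(set(process_map.unique()) - set(procs))
    if skipped:
        warnings.warn(f"processes with zero observed functions skipped: {skipped}",
                      stacklevel=2)
    proc_idx = {p: i for i, p in enumerate(procs)}
    onehot = np.zeros((len(funcs), len(procs)))
    for j, f in enumerate(funcs):
        onehot[j, proc_idx[process_map[f]]] = 1.0

    # ---- Fisher exact per process, pooled L vs H transects
    l_sites = [s for s in sites if design[s] == "L"]
    h_sites = [s for s in sites if design[s] == "H"]
    fisher_rows = []
    if l_sites and h_sites:
        pres_l = presence.loc[l_sites].max(axis=0)
        pres_h = presence.loc[h_sites].max(axis=0)
        for proc in procs:
            fs = [f for f in funcs if process_map[f] == proc]
            a = int(pres_l[fs].sum())
            b = len(fs) - a
            c = int(pres_h[fs].sum())
            d = len(fs) - c
            fisher_rows.append(
                {
                    "process": proc,
                    "present_L": a,
                    "absent_L": b,
                    "present_H": c,
                    "absent_H": d,
                    "p_value": fisher_exact_2x2([[a, b], [c, d]]),
                }
            )
    fisher = pd.DataFrame(
        fisher_rows,
        columns=["process", "present_L", "absent_L", "present_H", "absent_H", "p_value"],
    ).set_index("process")

    # ---- multiscale bootstrap of the site dendrogram on process counts
    M = _process_counts(P, onehot)
    Z = linkage(pdist(M, metric=metric), method=method)
    observed = sorted(_clades(Z, sites), key=lambda s: (len(s), sorted(s)))
    scales = np.asarray(list(scales), dtype=float)
    n_fun = len(funcs)
    hit = np.zeros((len(scales), len(observed)), dtype=int)
    for si, r in enumerate(scales):
        m = max(2, int(round(r * n_fun)))
        for _ in range(n_boot):
            idx = rng.integers(0, n_fun, size=m)
            Mb = _process_counts(P, onehot, idx)
            Zb = linkage(pdist(Mb, metric=metric), method=method)
            boot_clades = _clades(Zb, sites)
            for ci, clade in enumerate(observed):
                if clade in boot_clades:
                    hit[si, ci] += 1
    bp_curves = hit / n_boot
    rows = []
    one = int(np.argmin(np.abs(scales - 1.0)))
    for ci, clade in enumerate(observed):
        au, _ = _au_from_curve(scales, bp_curves[:, ci], n_boot)
        rows.append(
            {
                "clade": ",".join(sorted(clade)),
                "size": len(clade),
                "bp": float(bp_curves[one, ci]),
                "au": au,
            }
        )
    clades = pd.DataFrame(rows, columns=["clade", "size", "bp", "au"])
    return NutrientReport(
        fisher=fisher,
        clades=clades,
        linkage_matrix=Z,
        site_order=sites,
        skipped_processes=skipped,
    )
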