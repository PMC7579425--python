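"""Synthetic watershed dataset generator.

Emulates the statistical structure of a sediment-metagenome study of a
glacierized watershed: ~300 MAGs spread over 25 phyla, eight samples in four
location classes (two low-runoff sites L1/L2, two high-runoff sites H1/H2,
one negligible-runoff control C, three tributary soils S1-S3), per-sample
sequencing depth, and a tunable "runoff tilt" that lowers phylum-level
evenness in the high-runoff class.  The generator also emits matching
genome quality records, function annotations, pathway definitions and a
small regime-structured porewater/sediment geochemistry table, so every
downstream stage of the pipeline can be exercised without any sequencing
data.

Model
-----
* Genomes are partitioned over phyla by a stick-breaking split, so a few
  phyla dominate and several are singletons (a long tail is typical of MAG
  recovery).
* Phylum base proportions are one draw from Dirichlet(concentration / n_phyla
  * 1); low-runoff, control and soil classes share these proportions.
* High-runoff phylum proportions are the base proportions tilted by
  exp(-delta * rank), where rank orders phyla by decreasing base proportion,
  then renormalized.  Any delta > 0 strictly lowers the expected Pielou
  evenness of the H class; delta = 0 recovers the null.
* Within each phylum, genome weights are a flat Dirichlet draw shared across
  samples; a sample's counts are Multinomial(depth, class probabilities)
  with depth ~ Poisson(depth_per_sample).
* Each phylum owns a pool of functions; a genome carries each pool function
  independently with probability 0.7 (genome incompleteness).  A fraction
  ``oxidative_drop`` of the designated oxidative functions is removed from
  genomes of H-dominant phyla (those whose expected proportion rises under
  the tilt), mimicking the loss of oxidative metabolism under high
  sedimentation.
* Geochemistry features are Normal draws around class-specific means.

A ``Truth`` record retains every generating parameter, so expected phylum
proportions (and hence evenness) per class can be recomputed analytically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd

from .community import LOCATION_CLASSES, AbundanceTable

__all__ = [
    "SyntheticConfig",
    "Truth",
    "SyntheticDataset",
    "generate_dataset",
    "effective_evenness",
    "pielou_evenness",
    "tilt_for_evenness_ratio",
    "calibrate_runoff_tilt",
]

DEFAULT_SAMPLES: tuple[tuple[str, str], ...] = (
    ("L1", "L"),
    ("L2", "L"),
    ("H1", "H"),
    ("H2", "H"),
    ("C", "C"),
    ("S1", "S"),
    ("S2", "S"),
    ("S3", "S"),
)

# Fraction of the function vocabulary designated "oxidative".
OXIDATIVE_FRACTION = 0.3
# Probability that a genome carries any given function of its phylum pool.
FUNCTION_PRESENCE_PROB = 0.7
# Fraction of genomes drawn to fail the MIMAG quality filter.
MIMAG_FAIL_RATE = 0.1
# Stick-breaking Beta(1, alpha) parameter for phylum sizes.
STICK_ALPHA = 2.0

# Realistic-looking phylum names for readable outputs; padded with numbered
# phyla when n_phyla exceeds the list.
PHYLUM_NAMES = [
    "Proteobacteria", "Actinobacteriota", "Chloroflexota", "Planctomycetota",
    "Acidobacteriota", "Bacteroidota", "Verrucomicrobiota", "Desulfobacterota",
    "Gemmatimonadota", "Nitrospirota", "Eisenbacteria", "Patescibacteria",
    "Omnitrophota", "KSB1", "Armatimonadota", "Lindowbacteria", "UBP10",
    "Zixibacteria", "Myxococcota", "Spirochaetota", "Cyanobacteria",
    "Methylomirabilota", "Thermoplasmatota", "Halobacteriota", "Crenarchaeota",
]
ARCHAEAL_PHYLA = {"Thermoplasmatota", "Halobacteriota", "Crenarchaeota"}
PROTEO_CLASSES = ("Alphaproteobacteria", "Gammaproteobacteria")

# feature -> (mean L, mean H, mean C, mean S, sd); loosely modelled on
# oxygenated low-runoff porewaters vs reducing high-runoff porewaters.
GEOCHEM_MODEL: dict[str, tuple[float, float, float, float, float]] = {
    "pH":        (7.8,   7.5,   8.1,   7.0,  0.08),
    "O2":        (250.0, 60.0,  310.0, 35.0, 15.0),
    "redox":     (180.0, -40.0, 260.0, -10.0, 20.0),
    "NO2_NO3":   (8.0,   1.5,   12.0,  1.0,  0.8),
    "depth_m":   (150.0, 140.0, 50.0,  1.0,  8.0),
    "OC_pct":    (2.5,   1.2,   3.2,   1.0,  0.15),
    "CaCO3_pct": (5.0,   12.0,  3.0,   10.0, 0.6),
    "SO4":       (50.0,  180.0, 40.0,  160.0, 9.0),
    "NH3":       (2.0,   25.0,  1.0,   20.0, 1.2),
    "Cl":        (30.0,  38.0,  25.0,  42.0, 1.5),
}
_GEOCHEM_CLASS_COL = {"L": 0, "H": 1, "C": 2, "S": 3}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic watershed.

    ``runoff_tilt`` (delta) is the strength of the evenness loss injected in
    high-runoff samples; 0 means no effect.  ``concentration`` scales the
    Dirichlet draw of phylum base proportions (larger = more even
    communities).  ``function_pool_size`` is the number of functions in each
    phylum's pool; the global vocabulary is three times that.
    """

    n_genomes: int = 300
    n_phyla: int = 25
    samples: tuple[tuple[str, str], ...] = DEFAULT_SAMPLES
    depth_per_sample: float = 1_000_000.0
    concentration: float = 50.0
    runoff_tilt: float = 0.15
    function_pool_size: int = 40
    oxidative_drop: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be positive")
        if not 1 <= self.n_phyla <= self.n_genomes:
            raise ValueError("n_phyla must satisfy 1 <= n_phyla <= n_genomes")
        if self.depth_per_sample <= 0:
            raise ValueError("depth_per_sample must be positive")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if self.runoff_tilt < 0:
            raise ValueError("runoff_tilt must be >= 0")
        if not 0 <= self.oxidative_drop <= 1:
            raise ValueError("oxidative_drop must be in [0, 1]")
        if self.function_pool_size < 1:
            raise ValueError("function_pool_size must be positive")
        ids = [s for s, _ in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample ids must be unique")
        classes = {c for _, c in self.samples}
        unknown = classes - set(LOCATION_CLASSES)
        if unknown:
            raise ValueError(f"unknown location classes in samples: {sorted(unknown)}")


@dataclass
class Truth:
    """Generating parameters sufficient to recompute expectations."""

    base_proportions: pd.Series          # phylum -> base proportion
    class_phylum_props: pd.DataFrame     # phylum x class expected proportions
    genome_class_probs: pd.DataFrame     # genome x class sampling probabilities
    phylum_rank: pd.Series               # phylum -> rank (0 = most abundant)
    runoff_tilt: float
    h_dominant_phyla: list[str]
    oxidative_functions: list[str]
    function_processes: pd.Series        # function -> nutrient-cycle process

    def expected_phylum_proportions(self, location_class: str) -> pd.Series:
        if location_class not in self.class_phylum_props.columns:
            raise KeyError(f"unknown location class {location_class!r}")
        return self.class_phylum_props[location_class]

    def to_dict(self) -> dict:
        return {
            "runoff_tilt": self.runoff_tilt,
            "base_proportions": self.base_proportions.to_dict(),
            "class_phylum_props": {
                c: self.class_phylum_props[c].to_dict()
                for c in self.class_phylum_props.columns
            },
            "phylum_rank": {k: int(v) for k, v in self.phylum_rank.items()},
            "h_dominant_phyla": list(self.h_dominant_phyla),
            "oxidative_functions": list(self.oxidative_functions),
            "function_processes": self.function_processes.to_dict(),
        }


@dataclass
class SyntheticDataset:
    counts: AbundanceTable
    taxonomy: pd.DataFrame               # genome -> domain, phylum, class
    quality: pd.DataFrame                # genome -> completeness, contamination
    annotations: dict[str, set[str]]     # genome -> functions
    pathways: dict[str, set[str]]        # pathway -> enzymes
    geochem: pd.DataFrame                # sample x feature
    design: pd.Series                    # sample -> location class
    truth: Truth
    config: SyntheticConfig = field(repr=False, default=None)


def _stick_breaking_weights(rng: np.random.Generator, n: int) -> np.ndarray:
    if n == 1:
        rng.beta(1.0, STICK_ALPHA, size=0)  # keep stream layout stable
        return np.array([1.0])
    v = rng.beta(1.0, STICK_ALPHA, size=n - 1)
    w = np.empty(n)
    rem = 1.0
    for i, vi in enumerate(v):
        w[i] = vi * rem
        rem *= 1.0 - vi
    w[-1] = rem
    return w


def pielou_evenness(p: np.ndarray | pd.Series) -> float:
    """Shannon entropy of a proportion vector over its maximum ln(S).

    S counts all categories, including structural zeros.  A single-category
    vector is trivially even (returns 1.0).
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("need a non-empty 1-D proportion vector")
    if not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError("proportions must sum to 1")
    if len(p) == 1:
        return 1.0
    pos = p[p > 0]
    h = float(-(pos * np.log(pos)).sum())
    return h / np.log(len(p))


def _tilted_props(base: np.ndarray, ranks: np.ndarray, delta: float) -> np.ndarray:
    w = base * np.exp(-delta * ranks)
    return w / w.sum()


def effective_evenness(truth: Truth, location_class: str) -> float:
    """Pielou evenness of the expected phylum proportions for a class."""
    return pielou_evenness(truth.expected_phylum_proportions(location_class))


def tilt_for_evenness_ratio(
    base: np.ndarray | pd.Series,
    ranks: np.ndarray | pd.Series,
    target_ratio: float,
    tol: float = 1e-4,
    max_delta: float = 200.0,
) -> float:
    """Find delta so that evenness(tilted) / evenness(base) hits a target.

    Solved by bisection; the evenness ratio decreases monotonically in delta
    for the exponential rank tilt.  ``target_ratio`` must be in (0, 1].
    """
    if not 0 < target_ratio <= 1:
        raise ValueError("target_ratio must be in (0, 1]")
    base = np.asarray(base, dtype=float)
    ranks = np.asarray(ranks, dtype=float)
    e0 = pielou_evenness(base)

    def ratio(delta: float) -> float:
        return pielou_evenness(_tilted_props(base, ranks, delta)) / e0

    if ratio(0.0) <= target_ratio:
        return 0.0
    lo, hi = 0.0, 1.0
    while ratio(hi) > target_ratio:
        hi *= 2.0
        if hi > max_delta:
            raise ValueError("target evenness ratio unreachable by tilting")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if ratio(mid) > target_ratio:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def calibrate_runoff_tilt(
    config: SyntheticConfig, target_ratio: float
) -> SyntheticConfig:
    """Return a config whose tilt yields evenness(H)/evenness(L) ~= target.

    The phylum base proportions depend only on draws made before the tilt is
    applied, so generating a null (delta = 0) dataset with the same seed
    exposes the base proportions the calibrated dataset will share.
    """
    null = generate_dataset(replace(config, runoff_tilt=0.0))
    base = null.truth.base_proportions.to_numpy()
    ranks = null.truth.phylum_rank.to_numpy()
    delta = tilt_for_evenness_ratio(base, ranks, target_ratio)
    return replace(config, runoff_tilt=delta)


def _phylum_names(n: int) -> list[str]:
    names = PHYLUM_NAMES[:n]
    names += [f"Phylum{i:02d}" for i in range(len(names) + 1, n + 1)]
    return names


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Draw a complete synthetic dataset; byte-reproducible from the seed.

    One seed governs everything: a SeedSequence spawns an independent child
    stream per section (structure, counts, quality, annotations, pathways,
    geochemistry), so two configs differing only in ``runoff_tilt`` share
    identical phylum structure, taxonomy, quality and function-presence
    draws -- the tilt changes only what it models.
    """
    config.validate()
    children = np.random.SeedSequence(config.seed).spawn(6)
    rng, rng_counts, rng_quality, rng_ann, rng_pw, rng_geo = (
        np.random.default_rng(s) for s in children
    )
    n_g, n_p = config.n_genomes, config.n_phyla
    phyla = _phylum_names(n_p)

    # -- phylum sizes: one genome each, remainder by stick-breaking weights
    weights = _stick_breaking_weights(rng, n_p)
    sizes = np.ones(n_p, dtype=int)
    if n_g > n_p:
        sizes += rng.multinomial(n_g - n_p, weights)

    # -- phylum base proportions shared by L, C and S
    alpha = np.full(n_p, config.concentration / n_p)
    base = rng.dirichlet(alpha)
    base = np.clip(base, 1e-12, None)
    base /= base.sum()
    # rank 0 = most abundant phylum; ties broken by phylum index
    ranks = np.empty(n_p, dtype=int)
    ranks[np.lexsort((np.arange(n_p), -base))] = np.arange(n_p)
    h_props = _tilted_props(base, ranks, config.runoff_tilt)
    class_props = pd.DataFrame(
        {"L": base, "C": base, "S": base, "H": h_props}, index=pd.Index(phyla, name="phylum")
    )[list(LOCATION_CLASSES)]

    # -- genomes: ids, phylum membership, within-phylum weights
    phylum_of = np.repeat(np.arange(n_p), sizes)
    genome_ids = [f"MAG{i:04d}" for i in range(n_g)]
    within = np.empty(n_g)
    start = 0
    for p in range(n_p):
        within[start:start + sizes[p]] = rng.dirichlet(np.ones(sizes[p]))
        start += sizes[p]

    genome_probs = pd.DataFrame(
        {
            cls: class_props[cls].to_numpy()[phylum_of] * within
            for cls in LOCATION_CLASSES
        },
        index=pd.Index(genome_ids, name="genome"),
    )

    # -- taxonomy (Proteobacteria genomes get a class for the split option)
    proteo_cls = rng.choice(len(PROTEO_CLASSES), size=n_g)
    tax_rows = []
    for i, g in enumerate(genome_ids):
        phy = phyla[phylum_of[i]]
        domain = "Archaea" if phy in ARCHAEAL_PHYLA else "Bacteria"
        cls = PROTEO_CLASSES[proteo_cls[i]] if phy == "Proteobacteria" else ""
        tax_rows.append((g, domain, phy, cls))
    taxonomy = pd.DataFrame(
        tax_rows, columns=["genome", "domain", "phylum", "class"]
    ).set_index("genome")

    # -- counts: Multinomial(depth, class probabilities) per sample
    sample_ids = [s for s, _ in config.samples]
    design = pd.Series({s: c for s, c in config.samples}, name="location_class")
    design.index.name = "sample"
    cols = {}
    for s in sample_ids:
        depth = int(rng_counts.poisson(config.depth_per_sample))
        if depth <= 0:
            raise ValueError(
                f"drawn sequencing depth for sample {s} is zero; "
                "increase depth_per_sample"
            )
        cols[s] = rng_counts.multinomial(depth, genome_probs[design[s]].to_numpy())
    counts = AbundanceTable(
        pd.DataFrame(cols, index=pd.Index(genome_ids, name="genome")), mode="counts"
    )

    # -- quality: ~MIMAG_FAIL_RATE of genomes fail the filter
    u_fail = rng_quality.random(n_g)
    comp_pass = rng_quality.uniform(50.0, 100.0, n_g)
    comp_fail = rng_quality.uniform(20.0, 49.9, n_g)
    cont_pass = rng_quality.uniform(0.0, 9.5, n_g)
    cont_fail = rng_quality.uniform(10.0, 30.0, n_g)
    fail_by_cont = rng_quality.random(n_g) < 0.5
    failed = u_fail < MIMAG_FAIL_RATE
    completeness = np.where(failed & ~fail_by_cont, comp_fail, comp_pass)
    contamination = np.where(failed & fail_by_cont, cont_fail, cont_pass)
    quality = pd.DataFrame(
        {"completeness": completeness, "contamination": contamination},
        index=pd.Index(genome_ids, name="genome"),
    )

    # -- function vocabulary, phylum pools, per-genome annotations
    vocab_size = 3 * config.function_pool_size
    n_ox = max(1, int(round(OXIDATIVE_FRACTION * vocab_size)))
    vocab = [f"F{i:04d}" for i in range(vocab_size)]
    oxidative = vocab[:n_ox]
    cycles = ("carbon", "nitrogen", "sulfur")
    processes = pd.Series(
        {
            f: f"{cycles[i % 3]}_{'oxidation' if i < n_ox else 'reduction'}"
            for i, f in enumerate(vocab)
        },
        name="process",
    )
    pool_size = min(config.function_pool_size, vocab_size)
    pools = np.stack(
        [rng_ann.choice(vocab_size, size=pool_size, replace=False) for _ in range(n_p)]
    )
    presence_u = rng_ann.random((n_g, vocab_size))
    drop_u = rng_ann.random((n_g, vocab_size))
    h_dominant_idx = np.flatnonzero(h_props > base)
    h_dominant = [phyla[i] for i in h_dominant_idx] if config.runoff_tilt > 0 else []
    ox_idx = np.arange(n_ox)
    annotations: dict[str, set[str]] = {}
    for i, g in enumerate(genome_ids):
        pool = pools[phylum_of[i]]
        have = pool[presence_u[i, pool] < FUNCTION_PRESENCE_PROB]
        if config.runoff_tilt > 0 and phylum_of[i] in h_dominant_idx:
            keep = ~(
                np.isin(have, ox_idx) & (drop_u[i, have] < config.oxidative_drop)
            )
            have = have[keep]
        annotations[g] = {vocab[j] for j in have}

    # -- pathway definitions: random enzyme subsets of the vocabulary
    n_pathways = max(5, vocab_size // 4)
    pw_sizes = rng_pw.integers(3, 9, size=n_pathways)
    pathways = {
        f"PWY{i:03d}": {vocab[j] for j in rng_pw.choice(vocab_size, size=int(k), replace=False)}
        for i, k in enumerate(pw_sizes)
    }

    # -- geochemistry: Normal draws around class means
    geo = {
        feat: [
            rng_geo.normal(GEOCHEM_MODEL[feat][_GEOCHEM_CLASS_COL[design[s]]],
                       GEOCHEM_MODEL[feat][4])
            for s in sample_ids
        ]
        for feat in GEOCHEM_MODEL
    }
    geochem = pd.DataFrame(geo, index=pd.Index(sample_ids, name="sample"))

    truth = Truth(
        base_proportions=pd.Series(base, index=phyla, name="base"),
        class_phylum_props=class_props,
        genome_class_probs=genome_probs,
        phylum_rank=pd.Series(ranks, index=phyla, name="rank"),
        runoff_tilt=config.runoff_tilt,
        h_dominant_phyla=h_dominant,
        oxidative_functions=oxidative,
        function_processes=processes,
    )
    return SyntheticDataset(
        counts=counts,
        taxonomy=taxonomy,
        quality=quality,
        annotations=annotations,
        pathways=pathways,
        geochem=geochem,
        design=design,
        truth=truth,
        config=config,
    )
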