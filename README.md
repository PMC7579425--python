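# divshift

Does a shift from low- to high-runoff conditions reduce the diversity of the
dominant microbes in watershed sediments?  `divshift` is a Python package for
answering that question from metagenome-assembled genome (MAG) abundance
tables.  It is aimed at microbial ecologists working with glacierized or
high-latitude watersheds sampled along contrasting hydrological transects
(low-runoff sites L, high-runoff sites H, a negligible-runoff control C, and
tributary soils S), but the machinery applies to any design in which samples
fall into a small number of location classes.

## The statistic

Mapped-read counts per genome are depth-normalized within each sample,

p_gs = n_gs / Σ_g n_gs,

pooled by location class (summing counts across the class's samples, then
renormalizing) and tallied by phylum, giving a taxon × class proportion
profile **Y**.  The analysis then:

1. **orders** the classes by agglomerative clustering of the profile columns
   (average linkage, Euclidean distance), reading the leaf order off the merge
   tree so the tightest pair leads and later-joining classes append —
   e.g. L → C → H → S for the nested pattern (((L,C),H),S);
2. **regresses** each taxon's proportion on the ordered class ranks
   x = 0,…,m−1 by ordinary least squares.  With a single pooled value per
   class there is one point per class, so no per-taxon p-value exists, but
   the slope β̂_t = cov(x, y_t)/var(x) — and especially its sign — is well
   defined;
3. **tests** whether negative slopes are enriched with an exact one-sided
   binomial test: if k of n informative taxa (exact zeros excluded) have
   β̂ < 0, then under a fair-coin null

   P = P(X ≥ k), X ~ Binomial(n, ½) = Σ_{i≥k} C(n, i) / 2ⁿ,

   computed with exact integer coefficients (k = 19, n = 25 gives
   245506/2²⁵ ≈ 0.0073; k = 22 gives 2626/2²⁵ ≈ 7.8 × 10⁻⁵).

A small P means most taxa lose ground along the ordering — a systematic
diversity loss toward the high-runoff end, not noise in a few taxa.

The package also ships the two companion arms of the analysis:

* **functional potential** — a per-site abundance inclusion cutoff
  (−log₁₀ of each genome's max-scaled proportion ≤ 0.25), parsimony pathway
  inference (minimum set cover of each genome's enzymes, exact
  branch-and-bound for small instances), a (taxon, pathway) × class profile
  fed to the same sign-enrichment machinery, and comparisons of
  carbon/nitrogen/sulfur cycling between transects (exact Fisher tests plus a
  site dendrogram with multiscale/approximately-unbiased bootstrap support);
* **geochemistry** — unit-variance PCA of porewater/sediment chemistry, PAM
  clustering with silhouette-selected k, rank-based Dunn pairwise tests with
  Benjamini–Hochberg adjustment, and NMDS of Bray–Curtis community
  dissimilarities with permutation-tested environmental vectors (envfit);
* **synthetic watershed generator** — Dirichlet-multinomial communities over
  25 phyla with a tunable "runoff tilt" δ that lowers expected phylum
  evenness in the H class by exp(−δ·rank) re-weighting, plus matching
  taxonomy, MIMAG-style quality records, annotations, pathway definitions
  and regime-structured geochemistry, with an analytic truth record.

## Worked example

```python
from divshift import (SyntheticConfig, generate_dataset, calibrate_runoff_tilt,
                      effective_evenness, Dataset, taxa_shift_report)

# a watershed whose high-runoff evenness is 60% of the low-runoff evenness
cfg = calibrate_runoff_tilt(SyntheticConfig(seed=7), target_ratio=0.6)
ds = generate_dataset(cfg)
print(f"runoff tilt delta = {cfg.runoff_tilt:.3f}")
print(f"evenness L = {effective_evenness(ds.truth, 'L'):.3f}, "
      f"H = {effective_evenness(ds.truth, 'H'):.3f}")

bundle = Dataset(counts=ds.counts, taxonomy=ds.taxonomy,
                 quality=ds.quality, design=ds.design)
profile, report = taxa_shift_report(bundle)
print(f"class ordering: {' -> '.join(report.ordering.order)}")
e = report.enrichment
print(f"negative slopes: {e.k} of {e.n}  (one-sided binomial P = {e.p_value:.2e})")
```

prints

```
runoff tilt delta = 0.308
evenness L = 0.959, H = 0.576
class ordering: L -> S -> C -> H
negative slopes: 20 of 24  (one-sided binomial P = 7.72e-04)
```

H lands at the far end of the data-driven ordering, 20 of the 24 informative
phyla decline toward it, and the exact binomial tail calls that enrichment
highly significant — the injected diversity loss is recovered.  (One phylum
had an exactly zero slope and is excluded from n.)

## Command line

```sh
divshift simulate --out inputs/ --seed 1
divshift stat --counts inputs/counts.tsv --taxonomy inputs/taxonomy.tsv \
              --quality inputs/quality.tsv --design inputs/design.tsv \
              --out results/
divshift run-all --out results/ --seed 1      # simulate + all stages
```

All tables are plain TSV, dendrograms are Newick, reports are JSON.

## Layout

| module | contents |
| --- | --- |
| `divshift.synthetic` | watershed generator, truth record, evenness calibration |
| `divshift.community` | MIMAG filter, depth normalization, max-site assignment, class/taxon pooling |
| `divshift.stats` | class ordering, slopes, exact binomial sign enrichment |
| `divshift.functional` | inclusion cutoff, minimum set cover pathways, nutrient-cycle tests |
| `divshift.geochem` | unit-variance PCA, PAM + silhouette, Dunn/BH, NMDS + envfit |
| `divshift.io` / `divshift.workflow` / `divshift.cli` | TSV/JSON interchange, stage orchestration, CLI |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
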