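"""End-to-end pipeline stages and the run-all orchestrator.

Each ``*_report`` helper wires the lower-level modules together exactly as
the command-line verbs do, so library users and the CLI share one code
path.  ``run_all`` executes the requested stages in order
(simulate -> profile -> stat -> functions -> geochem), writes every
artifact under the configured output directory and returns a serializable
run report; any stage error is re-raised with the stage name attached.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import community, functional, geochem as geo, stats
from .community import AbundanceTable
from .io import Dataset, RunConfig, read_process_map, read_tables, write_dataset, write_tsv
from .synthetic import generate_dataset

__all__ = [
    "taxa_shift_report",
    "functional_shift_report",
    "geochem_report",
    "run_all",
    "taxa_rejection_rate",
]


def taxa_shift_report(
    dataset: Dataset,
    min_completeness: float = 50.0,
    max_contamination: float = 10.0,
    pooling: str = "sum",
    split_proteobacteria_by_class: bool = False,
    forced_order: list[str] | None = None,
    metric: str = "euclidean",
    linkage: str = "average",
    alternative: str = "greater",
) -> tuple[pd.DataFrame, stats.DivShiftReport]:
    """Taxonomic arm: filter MAGs, pool by class/taxon, run the shift test."""
    kept = community.filter_mags(
        dataset.quality,
        min_completeness=min_completeness,
        max_contamination=max_contamination,
        require=dataset.counts.genomes,
    )
    counts = dataset.counts.subset(kept)
    profile = community.aggregate_profile(
        counts,
        dataset.taxonomy,
        dataset.design,
        split_proteobacteria_by_class=split_proteobacteria_by_class,
        pooling=pooling,
    )
    report = stats.run_divshift(
        profile,
        forced_order=forced_order,
        metric=metric,
        method=linkage,
        alternative=alternative,
    )
    return profile, report


def functional_shift_report(
    dataset: Dataset,
    min_completeness: float = 50.0,
    max_contamination: float = 10.0,
    cutoff: float = 0.25,
    transform: str = "max_scaled",
    require_multi_hit: bool = True,
    split_proteobacteria_by_class: bool = True,
    forced_order: list[str] | None = None,
    metric: str = "euclidean",
    linkage: str = "average",
) -> tuple[pd.DataFrame, stats.DivShiftReport, dict[str, set[str]]]:
    """Functional arm: inclusion cutoff, pathway calls, shift test."""
    if dataset.annotations is None or dataset.pathways is None:
        raise ValueError("functional stage needs annotations and pathway definitions")
    kept = community.filter_mags(
        dataset.quality,
        min_completeness=min_completeness,
        max_contamination=max_contamination,
        require=dataset.counts.genomes,
    )
    props = community.normalize_abundance(dataset.counts.subset(kept))
    included = functional.include_genomes_per_site(props, cutoff=cutoff, transform=transform)
    calls = functional.call_pathways(
        {g: fs for g, fs in dataset.annotations.items() if g in kept},
        dataset.pathways,
        require_multi_hit=require_multi_hit,
    )
    profile = functional.build_pathway_profile(
        included,
        calls,
        dataset.taxonomy,
        dataset.design,
        split_proteobacteria_by_class=split_proteobacteria_by_class,
    )
    report = functional.functional_divshift(
        profile, forced_order=forced_order, metric=metric, method=linkage
    )
    return profile, report, included


def geochem_report(
    dataset: Dataset,
    community_profile: pd.DataFrame | None = None,
    n_perm: int = 999,
    n_restarts: int = 20,
    alpha: float = 0.025,
    seed: int = 0,
) -> dict:
    """Geochemistry arm: PCA + PAM, per-feature Dunn tests, NMDS envfit."""
    if dataset.geochem is None:
        raise ValueError("geochem stage needs a geochemistry table")
    table = dataset.geochem
    pca = geo.pca_unit_variance(table)
    pam_res = geo.pam_silhouette(pca.scores)
    dunn = {}
    classes = dataset.design[table.index]
    if classes.value_counts().min() >= 2:
        for feat in table.columns:
            dunn[feat] = geo.dunn_bh(table[feat].to_numpy(), classes.to_numpy(), alpha=alpha)
    else:
        warnings.warn(
            "some location classes have <2 geochem samples; Dunn tests skipped",
            stacklevel=2,
        )
    nmds = None
    if community_profile is None and dataset.counts is not None:
        community_profile = community.normalize_abundance(dataset.counts)
    if community_profile is not None:
        comm = community_profile
        if isinstance(comm, AbundanceTable):
            comm = comm.data
        # accept samples-in-columns (genome x sample) or samples-in-rows
        if set(comm.columns) >= set(table.index):
            comm = comm.T
        comm = comm.loc[table.index]
        nmds = geo.nmds_envfit(
            comm, table, n_perm=n_perm, seed=seed, n_restarts=n_restarts
        )
    return {"pca": pca, "pam": pam_res, "dunn": dunn, "nmds": nmds}


def taxa_rejection_rate(
    n_reps: int = 200,
    seed: int = 0,
    evenness_ratio: float | None = None,
    alpha: float = 0.05,
    config=None,
) -> dict:
    """Monte-Carlo rejection rate of the full taxa pipeline.

    Draws ``n_reps`` synthetic watersheds and runs filter -> normalize ->
    pool -> cluster-order -> slopes -> sign test on each.  With
    ``evenness_ratio`` set (e.g. 0.6), every replicate's runoff tilt is
    calibrated so the expected H-class evenness is that fraction of the
    L-class evenness, and a rejection additionally requires the
    directionally correct detection: negative-slope enrichment at
    ``p <= alpha`` with H ordered after L.  Without it the null
    (tilt = 0) is simulated and a rejection is simply ``p <= alpha``,
    measuring the type-I error of the whole data-driven procedure.
    """
    from dataclasses import replace

    from .synthetic import SyntheticConfig, calibrate_runoff_tilt

    base_cfg = config or SyntheticConfig()
    rep_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_reps)
    rejections = 0
    ks = []
    for s in rep_seeds:
        cfg = replace(base_cfg, seed=int(s), runoff_tilt=0.0)
        if evenness_ratio is not None:
            cfg = calibrate_runoff_tilt(cfg, evenness_ratio)
        ds = generate_dataset(cfg)
        bundle = Dataset(
            counts=ds.counts, taxonomy=ds.taxonomy, quality=ds.quality,
            design=ds.design,
        )
        _, rep = taxa_shift_report(bundle)
        ks.append(rep.enrichment.k)
        hit = rep.enrichment.p_value <= alpha
        if evenness_ratio is not None:
            order = rep.ordering.order
            hit = hit and order.index("H") > order.index("L")
        rejections += hit
    return {
        "rate": rejections / n_reps,
        "n_reps": n_reps,
        "alpha": alpha,
        "mean_k_negative": float(np.mean(ks)),
        "evenness_ratio": evenness_ratio,
    }


def _stage_error(stage: str, err: Exception) -> RuntimeError:
    return RuntimeError(f"stage {stage!r} failed: {err}")


def run_all(config: RunConfig) -> dict:
    """Execute the configured stages, write artifacts, return the report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(config.stages)
    report: dict = {"config": config.to_dict(), "stages": {}, "warnings": []}
    if config.transform == "raw":
        report["warnings"].append(
            "inclusion cutoff interpreted on raw proportions; the max-scaled "
            "reading is the default and far more permissive"
        )

    cfg = config
    if "simulate" in stages:
        try:
            ds_syn = generate_dataset(config.synthetic_config())
            paths = write_dataset(ds_syn, outdir / "inputs")
        except Exception as err:
            raise _stage_error("simulate", err) from err
        opts = dict(config.to_dict())
        opts.update({k: str(paths[k]) for k in
                     ("counts", "taxonomy", "quality", "design",
                      "annotations", "pathways", "geochem")})
        cfg = RunConfig(options=opts)
        report["stages"]["simulate"] = {
            "n_genomes": int(ds_syn.counts.data.shape[0]),
            "n_samples": int(ds_syn.counts.data.shape[1]),
            "runoff_tilt": ds_syn.truth.runoff_tilt,
        }

    dataset = read_tables(cfg)

    profile = None
    if "profile" in stages:
        try:
            profile, taxa_rep = taxa_shift_report(
                dataset,
                min_completeness=cfg.min_completeness,
                max_contamination=cfg.max_contamination,
                pooling=cfg.pooling,
                split_proteobacteria_by_class=cfg.split_proteobacteria_by_class,
                forced_order=cfg.forced_order,
                metric=cfg.metric,
                linkage=cfg.linkage,
                alternative=cfg.alternative,
            )
        except Exception as err:
            raise _stage_error("profile", err) from err
        write_tsv(profile, outdir / "taxon_profile.tsv", index_label="taxon")
        report["stages"]["profile"] = {
            "n_taxa": int(profile.shape[0]),
            "classes": list(profile.columns),
        }
        if "stat" in stages:
            write_tsv(taxa_rep.slopes, outdir / "taxa_slopes.tsv", index_label="taxon")
            if taxa_rep.ordering.linkage_matrix is not None:
                (outdir / "taxa_dendrogram.nwk").write_text(
                    taxa_rep.ordering.to_newick() + "\n"
                )
            with open(outdir / "taxa_enrichment.json", "w") as fh:
                json.dump(taxa_rep.to_dict(), fh, indent=1)
            report["stages"]["stat"] = taxa_rep.to_dict()
    elif "stat" in stages:
        raise _stage_error("stat", ValueError("stat requires the profile stage"))

    if "functions" in stages:
        try:
            fprofile, frep, included = functional_shift_report(
                dataset,
                min_completeness=cfg.min_completeness,
                max_contamination=cfg.max_contamination,
                cutoff=cfg.cutoff,
                transform=cfg.transform,
                require_multi_hit=cfg.require_multi_hit,
                split_proteobacteria_by_class=True,
                forced_order=cfg.forced_order,
                metric=cfg.metric,
                linkage=cfg.linkage,
            )
        except Exception as err:
            raise _stage_error("functions", err) from err
        write_tsv(
            fprofile.reset_index().set_index("taxon"),
            outdir / "pathway_profile.tsv",
        )
        inc = pd.DataFrame(
            [(s, g) for s in included for g in sorted(included[s])],
            columns=["sample", "genome"],
        )
        inc.to_csv(outdir / "included_genomes.tsv", sep="\t", index=False)
        with open(outdir / "functional_enrichment.json", "w") as fh:
            json.dump(frep.to_dict(), fh, indent=1)
        report["stages"]["functions"] = frep.to_dict()

        if cfg.options.get("process_map"):
            try:
                pmap = read_process_map(cfg.process_map)
                props = community.normalize_abundance(dataset.counts)
                pres = _presence_by_site(dataset, included)
                pres = pres[[f for f in pres.columns if f in set(pmap.index)]]
                nut = functional.compare_nutrient_processes(
                    pres, pmap, dataset.design, n_boot=cfg.n_boot, seed=cfg.seed
                )
            except Exception as err:
                raise _stage_error("functions", err) from err
            with open(outdir / "nutrient_processes.json", "w") as fh:
                json.dump(nut.to_dict(), fh, indent=1)
            report["stages"]["nutrient_processes"] = {
                "n_processes": int(nut.fisher.shape[0]),
                "skipped": nut.skipped_processes,
            }

    if "geochem" in stages:
        try:
            res = geochem_report(
                dataset,
                community_profile=None,  # genome-level sample proportions
                n_perm=cfg.n_perm,
                n_restarts=cfg.n_restarts,
                alpha=cfg.alpha,
                seed=cfg.seed,
            )
        except Exception as err:
            raise _stage_error("geochem", err) from err
        write_tsv(res["pca"].scores, outdir / "pca_scores.tsv", index_label="sample")
        write_tsv(res["pca"].loadings, outdir / "pca_loadings.tsv", index_label="feature")
        res["pam"].labels.to_frame().to_csv(
            outdir / "geochem_clusters.tsv", sep="\t", index_label="sample"
        )
        if res["dunn"]:
            pd.concat(res["dunn"], names=["feature"]).to_csv(
                outdir / "dunn_tests.tsv", sep="\t"
            )
        geo_summary = {
            "variance_fractions": res["pca"].variance_fractions.to_dict(),
            "pam_k": res["pam"].k,
            "silhouettes": res["pam"].silhouettes,
        }
        if res["nmds"] is not None:
            with open(outdir / "envfit.json", "w") as fh:
                json.dump(
                    {
                        "stress": res["nmds"].stress,
                        "converged": res["nmds"].converged,
                        "fits": res["nmds"].fits.reset_index().to_dict(orient="records"),
                    },
                    fh,
                    indent=1,
                )
            geo_summary["nmds_stress"] = res["nmds"].stress
        report["stages"]["geochem"] = geo_summary

    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return report


def _presence_by_site(dataset: Dataset, included: dict[str, set[str]]) -> pd.DataFrame:
    """Site x function presence among the genomes included at each site."""
    funcs = sorted(set().union(*dataset.annotations.values())) if dataset.annotations else []
    rows = {}
    for site, genomes in included.items():
        have = set()
        for g in genomes:
            have |= dataset.annotations.get(g, set())
        rows[site] = [1 if f in have else 0 for f in funcs]
    return pd.DataFrame.from_dict(rows, orient="index", columns=funcs)
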