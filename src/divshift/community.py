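"""Genome-level community composition.

This module owns the first, deterministic half of the pipeline: MIMAG-style
quality filtering of metagenome-assembled genomes (MAGs), sequencing-depth
normalization of mapped-read counts, assignment of each genome to the sample
where it is most abundant, and pooling of genome proportions into a
taxon x location-class profile that the downstream shift statistic consumes.

Conventions
-----------
Abundance tables are genome x sample :class:`pandas.DataFrame` objects wrapped
in :class:`AbundanceTable`, which records whether the values are raw mapped-read
counts or per-sample proportions.  Location classes follow the watershed
design: ``L`` (low runoff), ``H`` (high runoff), ``C`` (negligible-runoff
control) and ``S`` (tributary soils).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "LOCATION_CLASSES",
    "PROTEOBACTERIA",
    "AbundanceTable",
    "filter_mags",
    "normalize_abundance",
    "assign_max_site",
    "aggregate_profile",
    "validate_design",
]

#: Recognised location classes (low runoff, high runoff, control, soil).
LOCATION_CLASSES = ("L", "H", "C", "S")

#: Phylum that is split by class in the functional arm.
PROTEOBACTERIA = "Proteobacteria"

_PROP_TOL = 1e-9


class AbundanceTable:
    """A genome x sample abundance matrix in count or proportion mode.

    Parameters
    ----------
    data
        Genome (rows) x sample (columns) table of non-negative numbers.
    mode
        ``"counts"`` for raw mapped-read counts, ``"proportions"`` for
        depth-normalized values (each column must then sum to 1 within 1e-9).
    """

    def __init__(self, data: pd.DataFrame, mode: str = "counts"):
        data = pd.DataFrame(data)
        if mode not in ("counts", "proportions"):
            raise ValueError(f"mode must be 'counts' or 'proportions', got {mode!r}")
        if data.index.has_duplicates:
            dupes = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate genome ids: {dupes}")
        if data.columns.has_duplicates:
            dupes = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        values = data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("abundance table contains non-finite values")
        if (values < 0).any():
            bad = data.columns[(values < 0).any(axis=0)].tolist()
            raise ValueError(f"negative abundances in samples: {bad}")
        if mode == "proportions":
            sums = values.sum(axis=0)
            off = np.abs(sums - 1.0) > _PROP_TOL
            if off.any():
                bad = data.columns[off].tolist()
                raise ValueError(
                    f"proportion columns do not sum to 1 within {_PROP_TOL}: {bad}"
                )
        self.data = data
        self.mode = mode

    @property
    def is_proportions(self) -> bool:
        return self.mode == "proportions"

    @property
    def genomes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    def subset(self, genomes: Iterable[str]) -> "AbundanceTable":
        """Row-subset the table, keeping count mode; proportion tables are
        re-expressed as counts of themselves (columns no longer sum to 1)."""
        keep = [g for g in self.data.index if g in set(genomes)]
        return AbundanceTable(self.data.loc[keep], mode="counts")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        r, c = self.data.shape
        return f"AbundanceTable({r} genomes x {c} samples, mode={self.mode!r})"


def validate_design(design: Mapping[str, str] | pd.Series, samples: Iterable[str]) -> pd.Series:
    """Check that every sample maps to exactly one known location class."""
    design = pd.Series(dict(design) if not isinstance(design, pd.Series) else design)
    missing = [s for s in samples if s not in design.index]
    if missing:
        raise ValueError(f"samples missing from design: {missing}")
    unknown = sorted(set(design) - set(LOCATION_CLASSES))
    if unknown:
        raise ValueError(
            f"unknown location classes {unknown}; expected one of {LOCATION_CLASSES}"
        )
    return design


def filter_mags(
    quality: pd.DataFrame,
    min_completeness: float = 50.0,
    max_contamination: float = 10.0,
    require: Iterable[str] | None = None,
) -> set[str]:
    """Apply the MIMAG medium/high-quality filter to a genome quality table.

    A genome is kept when ``completeness >= min_completeness`` and
    ``contamination < max_contamination`` (strict upper bound).

    Parameters
    ----------
    quality
        DataFrame indexed by genome id with ``completeness`` and
        ``contamination`` columns, both in percent.
    require
        Optional genome ids (e.g. the rows of an abundance table) that must
        all be present in ``quality``; missing ids raise an error listing them.
    """
    if len(quality) == 0:
        raise ValueError("quality table is empty")
    for col in ("completeness", "contamination"):
        if col not in quality.columns:
            raise ValueError(f"quality table lacks required column {col!r}")
    comp = quality["completeness"].astype(float)
    cont = quality["contamination"].astype(float)
    if ((comp < 0) | (comp > 100)).any():
        bad = quality.index[(comp < 0) | (comp > 100)].tolist()
        raise ValueError(f"completeness outside [0, 100] for: {bad}")
    if (cont < 0).any():
        bad = quality.index[cont < 0].tolist()
        raise ValueError(f"negative contamination for: {bad}")
    if require is not None:
        missing = sorted(set(require) - set(quality.index))
        if missing:
            raise ValueError(f"genomes absent from quality table: {missing}")
    keep = (comp >= min_completeness) & (cont < max_contamination)
    return set(quality.index[keep])


def normalize_abundance(counts: AbundanceTable) -> AbundanceTable:
    """Convert mapped-read counts to per-sample proportions.

    Each cell is divided by its column total -- reads mapped to the genome
    over total reads mapped in that sample -- making genomes comparable
    across samples with different sequencing depths.
    """
    if counts.is_proportions:
        raise ValueError("table is already in proportion mode")
    sums = counts.data.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"all-zero sample columns: {zero.index.tolist()}")
    return AbundanceTable(counts.data.div(sums, axis=1), mode="proportions")


def assign_max_site(props: AbundanceTable) -> pd.Series:
    """Map each genome to the sample where it is most abundant.

    Ties are broken toward the lexicographically smallest sample id; the tie
    rule is part of the contract so downstream ordinations are reproducible.
    """
    if not props.is_proportions:
        raise ValueError("assign_max_site requires a proportion-mode table")
    data = props.data[sorted(props.data.columns)]
    all_zero = data.sum(axis=1) <= 0
    if all_zero.any():
        raise ValueError(
            f"genomes with zero abundance in every sample: {data.index[all_zero].tolist()}"
        )
    # idxmax returns the first (lexicographically smallest, post-sort) argmax
    return data.idxmax(axis=1).rename("site")


def _taxon_labels(
    taxonomy: pd.DataFrame | pd.Series,
    genomes: Iterable[str],
    split_proteobacteria_by_class: bool,
) -> pd.Series:
    if isinstance(taxonomy, pd.Series):
        tax = taxonomy.to_frame("phylum")
    else:
        tax = taxonomy
    if "phylum" not in tax.columns:
        raise ValueError("taxonomy must provide a 'phylum' column")
    missing = sorted(set(genomes) - set(tax.index))
    if missing:
        raise ValueError(f"genomes missing from taxonomy: {missing}")
    labels = tax.loc[list(genomes), "phylum"].astype(str).copy()
    if split_proteobacteria_by_class:
        if "class" not in tax.columns:
            raise ValueError(
                "split_proteobacteria_by_class requires a 'class' taxonomy column"
            )
        proteo = labels == PROTEOBACTERIA
        cls = tax.loc[list(genomes), "class"].astype(str)
        labels[proteo] = cls[proteo].where(cls[proteo].str.len() > 0, PROTEOBACTERIA)
    return labels


def aggregate_profile(
    table: AbundanceTable,
    taxonomy: pd.DataFrame | pd.Series,
    design: Mapping[str, str] | pd.Series,
    split_proteobacteria_by_class: bool = False,
    pooling: str = "sum",
) -> pd.DataFrame:
    """Pool samples into location classes and genomes into taxa.

    With ``pooling="sum"`` (default) raw counts are summed across the samples
    of each class and the pooled columns renormalized, which weights samples
    by their sequencing depth.  With ``pooling="mean"`` per-sample proportions
    are averaged within each class and renormalized, weighting samples
    equally.  Genome proportions are then summed within each taxon; taxa with
    zero abundance in a class keep an explicit 0 row so taxon sets stay
    aligned across classes.

    Returns
    -------
    pandas.DataFrame
        Taxon x location-class profile; every column sums to 1.
    """
    if pooling not in ("sum", "mean"):
        raise ValueError(f"pooling must be 'sum' or 'mean', got {pooling!r}")
    design = validate_design(design, table.samples)
    if pooling == "sum" and table.is_proportions:
        # summing proportions then renormalizing is the equal-weight pool
        warnings.warn(
            "sum pooling on a proportion-mode table weights samples equally; "
            "pass raw counts for depth-aware pooling",
            stacklevel=2,
        )
    if pooling == "mean" and not table.is_proportions:
        table = normalize_abundance(table)

    data = table.data
    classes = list(dict.fromkeys(design[s] for s in data.columns))
    pooled = {}
    for cls in classes:
        cols = [s for s in data.columns if design[s] == cls]
        pooled[cls] = data[cols].sum(axis=1) if pooling == "sum" else data[cols].mean(axis=1)
    pooled = pd.DataFrame(pooled)
    sums = pooled.sum(axis=0)
    if (sums <= 0).any():
        raise ValueError(
            f"location classes with zero pooled abundance: {sums.index[sums <= 0].tolist()}"
        )
    pooled = pooled.div(sums, axis=1)

    labels = _taxon_labels(taxonomy, pooled.index, split_proteobacteria_by_class)
    profile = pooled.groupby(labels).sum()
    profile = profile.div(profile.sum(axis=0), axis=1)  # guard rounding drift
    profile.index.name = "taxon"
    profile.columns.name = "location_class"
    return profile
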