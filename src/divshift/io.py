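"""Table readers/writers and run configuration.

All interchange is plain text: tab-separated tables (UTF-8, ``#`` comment
lines), Newick for dendrograms, JSON for reports and the generator truth
record.  Readers validate headers, numeric ranges and cross-file genome /
sample id consistency and report offending line numbers or ids.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
import pandas as pd
import yaml

from .community import AbundanceTable, validate_design
from .synthetic import SyntheticConfig, SyntheticDataset

__all__ = [
    "RunConfig",
    "Dataset",
    "read_counts",
    "read_taxonomy",
    "read_quality",
    "read_annotations",
    "read_pathway_definitions",
    "read_geochem",
    "read_design",
    "read_process_map",
    "read_tables",
    "write_dataset",
    "write_tsv",
]

_TSV_KW = dict(sep="\t", comment="#")


def write_tsv(df: pd.DataFrame, path: str | Path, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def _read_table(path: str | Path, index_col: str, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, index_col=0, **_TSV_KW)
    except pd.errors.ParserError as err:
        raise ValueError(f"{path}: malformed TSV ({err})") from err
    if df.index.name != index_col:
        raise ValueError(
            f"{path}: expected first column {index_col!r}, found {df.index.name!r}"
        )
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def _require_numeric(df: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    try:
        return df.astype(float)
    except (TypeError, ValueError):
        for i, (idx, row) in enumerate(df.iterrows(), start=2):
            if not all(_is_number(v) for v in row):
                raise ValueError(f"{path}: non-numeric value near line {i} (row {idx!r})")
        raise


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def read_counts(path: str | Path) -> AbundanceTable:
    df = _require_numeric(_read_table(path, "genome", []), path)
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative counts present")
    return AbundanceTable(df, mode="counts")


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    df = _read_table(path, "genome", ["phylum"])
    if "class" in df.columns:
        df["class"] = df["class"].fillna("")
    return df


def read_quality(path: str | Path) -> pd.DataFrame:
    df = _read_table(path, "genome", ["completeness", "contamination"])
    return _require_numeric(df[["completeness", "contamination"]], path)


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Long-format genome<TAB>function table to genome -> function set."""
    df = pd.read_csv(path, **_TSV_KW)
    for col in ("genome", "function"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return {g: set(sub["function"]) for g, sub in df.groupby("genome")}


def read_pathway_definitions(path: str | Path) -> dict[str, set[str]]:
    df = pd.read_csv(path, **_TSV_KW)
    for col in ("pathway", "enzyme"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    defs = {p: set(sub["enzyme"]) for p, sub in df.groupby("pathway")}
    empty = [p for p, es in defs.items() if not es]
    if empty:
        raise ValueError(f"{path}: pathways with no enzymes: {empty}")
    return defs


def read_geochem(path: str | Path) -> pd.DataFrame:
    return _require_numeric(_read_table(path, "sample", []), path)


def read_design(path: str | Path) -> pd.Series:
    df = _read_table(path, "sample", ["location_class"])
    return df["location_class"].astype(str)


def read_process_map(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, **_TSV_KW)
    for col in ("function", "process"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return df.set_index("function")["process"]


@dataclass
class Dataset:
    """Validated in-memory bundle of all pipeline inputs."""

    counts: AbundanceTable
    taxonomy: pd.DataFrame
    quality: pd.DataFrame
    design: pd.Series
    annotations: dict[str, set[str]] | None = None
    pathways: dict[str, set[str]] | None = None
    geochem: pd.DataFrame | None = None

    def validate(self) -> None:
        genomes = set(self.counts.genomes)
        for name, ids in (
            ("taxonomy", set(self.taxonomy.index)),
            ("quality", set(self.quality.index)),
        ):
            missing = sorted(genomes - ids)
            if missing:
                raise ValueError(f"genomes absent from {name}: {missing}")
        validate_design(self.design, self.counts.samples)
        if self.annotations is not None:
            stray = sorted(set(self.annotations) - genomes)
            if stray:
                raise ValueError(f"annotated genomes absent from counts: {stray}")
        if self.geochem is not None:
            missing = sorted(set(self.geochem.index) - set(self.design.index))
            if missing:
                raise ValueError(f"geochem samples absent from design: {missing}")


_CONFIG_FIELDS: dict[str, object] = {
    # input paths (None = stage unavailable unless simulated)
    "counts": None,
    "taxonomy": None,
    "quality": None,
    "design": None,
    "annotations": None,
    "pathways": None,
    "geochem": None,
    "process_map": None,
    # stage list and output directory
    "stages": ("profile", "stat"),
    "outdir": "divshift_out",
    # community tunables
    "min_completeness": 50.0,
    "max_contamination": 10.0,
    "pooling": "sum",
    "split_proteobacteria_by_class": False,
    # shift-statistic tunables
    "metric": "euclidean",
    "linkage": "average",
    "forced_order": None,
    "alternative": "greater",
    # functional tunables
    "cutoff": 0.25,
    "transform": "max_scaled",
    "require_multi_hit": True,
    "n_boot": 1000,
    # geochem tunables
    "n_perm": 999,
    "n_restarts": 20,
    "alpha": 0.025,
    # simulation overrides (passed to SyntheticConfig)
    "simulate": None,
    # global seed
    "seed": 0,
}


@dataclass
class RunConfig:
    """Validated run configuration; unknown keys are rejected on load."""

    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = sorted(set(self.options) - set(_CONFIG_FIELDS))
        if unknown:
            raise ValueError(f"unknown configuration keys: {unknown}")
        merged = dict(_CONFIG_FIELDS)
        merged.update({k: v for k, v in self.options.items() if v is not None or k in self.options})
        self.options = merged

    def __getattr__(self, name: str):
        opts = object.__getattribute__(self, "options")
        if name in opts:
            return opts[name]
        raise AttributeError(name)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: configuration must be a mapping")
        return cls(options=raw)

    def synthetic_config(self) -> SyntheticConfig:
        overrides = dict(self.simulate or {})
        overrides.setdefault("seed", self.seed)
        known = {f.name for f in dataclasses.fields(SyntheticConfig)}
        unknown = sorted(set(overrides) - known)
        if unknown:
            raise ValueError(f"unknown simulate keys: {unknown}")
        if "samples" in overrides:
            overrides["samples"] = tuple(tuple(x) for x in overrides["samples"])
        return SyntheticConfig(**overrides)

    def to_dict(self) -> dict:
        return dict(self.options)


def read_tables(config: RunConfig) -> Dataset:
    """Load and cross-validate every input the configured stages need."""
    for key in ("counts", "taxonomy", "quality", "design"):
        if config.options.get(key) is None:
            raise ValueError(f"configuration lacks required input path {key!r}")
    ds = Dataset(
        counts=read_counts(config.counts),
        taxonomy=read_taxonomy(config.taxonomy),
        quality=read_quality(config.quality),
        design=read_design(config.design),
        annotations=read_annotations(config.annotations) if config.annotations else None,
        pathways=read_pathway_definitions(config.pathways) if config.pathways else None,
        geochem=read_geochem(config.geochem) if config.geochem else None,
    )
    ds.validate()
    return ds


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the seven input TSVs plus the truth JSON; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "quality": outdir / "quality.tsv",
        "annotations": outdir / "annotations.tsv",
        "pathways": outdir / "pathways.tsv",
        "geochem": outdir / "geochem.tsv",
        "design": outdir / "design.tsv",
        "truth": outdir / "truth.json",
    }
    write_tsv(dataset.counts.data, paths["counts"], index_label="genome")
    write_tsv(dataset.taxonomy, paths["taxonomy"], index_label="genome")
    write_tsv(dataset.quality, paths["quality"], index_label="genome")
    ann = pd.DataFrame(
        [(g, f) for g in sorted(dataset.annotations) for f in sorted(dataset.annotations[g])],
        columns=["genome", "function"],
    )
    ann.to_csv(paths["annotations"], sep="\t", index=False)
    pws = pd.DataFrame(
        [(p, e) for p in sorted(dataset.pathways) for e in sorted(dataset.pathways[p])],
        columns=["pathway", "enzyme"],
    )
    pws.to_csv(paths["pathways"], sep="\t", index=False)
    write_tsv(dataset.geochem, paths["geochem"], index_label="sample")
    dataset.design.rename("location_class").to_frame().to_csv(
        paths["design"], sep="\t", index_label="sample"
    )
    with open(paths["truth"], "w") as fh:
        json.dump(dataset.truth.to_dict(), fh, indent=1)
    return paths
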