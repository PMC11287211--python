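"""Readers, writers and validation for the package's plain-text formats.

All formats are tab-separated (annotation and feature tables) or CSV
(bioassay plates, extraction series), UTF-8, header required. Validation
collects every violation and reports them together rather than failing on
the first.

Formats
-------
annotations.tsv   genome_id  domain  lineage  annotation_id   (one row per detection)
counts.tsv        zotu_id  <sample...>                         (integer counts)
taxonomy.tsv      zotu_id  lineage                             (semicolon ranks)
metadata.tsv      sample_id  medium  corrinoid  timepoint  replicate  inoculated
series.csv        round, aq_conc_nM[, censored[, lod_nM]]
plate.csv         sample_id, od600
standards.csv     conc_nM, od600
markers.yaml      biosynthesis_markers / dependent_markers / independent_alternatives
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from .community import RANKS, FeatureTable
from .genome_roles import GenomeAnnotation, MarkerConfig, parse_lineage
from .partition import ExtractionGeometry, ExtractionRound, ExtractionSeries

__all__ = [
    "ValidationError",
    "RunConfig",
    "read_annotations",
    "write_annotations",
    "read_feature_table",
    "write_feature_table",
    "read_series",
    "write_series",
    "read_marker_config",
    "write_marker_config",
    "read_plate",
    "read_standards",
]


class ValidationError(ValueError):
    """Input fails validation; message lists every problem found."""

    def __init__(self, problems: Iterable[str]):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


@dataclass(frozen=True)
class RunConfig:
    """Flat run configuration shared by the CLI subcommands."""

    alpha: float = 0.05
    n_perm: int = 999
    seed: int = 0
    vol_aq: float = 0.01
    vol_soil: float = 0.001
    soil_mass: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError([f"alpha must be in (0,1), got {self.alpha}"])

    @property
    def geometry(self) -> ExtractionGeometry:
        return ExtractionGeometry(self.vol_aq, self.vol_soil, self.soil_mass)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError([f"unknown config keys: {sorted(unknown)}"])
        return cls(**data)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ["genome_id", "domain", "lineage", "annotation_id"]


def read_annotations(path: str | Path) -> list[GenomeAnnotation]:
    """Read a long-format annotation table into per-genome marker sets.

    Duplicate (genome_id, annotation_id) rows collapse into one set element.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    problems = []
    missing = set(ANNOTATION_COLUMNS) - set(frame.columns)
    if missing:
        raise ValidationError([f"annotation table lacks columns: {sorted(missing)}"])
    if frame["genome_id"].isna().any() or (frame["genome_id"] == "").any():
        problems.append("empty genome_id values present")
    bad_domain = set(frame["domain"].dropna()) - {"bacteria", "archaea"}
    if bad_domain:
        problems.append(f"unknown domain values: {sorted(bad_domain)}")
    if problems:
        raise ValidationError(problems)

    genomes = []
    for gid, grp in frame.groupby("genome_id", sort=True):
        detected = frozenset(grp["annotation_id"].dropna())
        lineage = parse_lineage(grp["lineage"].iloc[0] if grp["lineage"].notna().any() else "")
        genomes.append(
            GenomeAnnotation(
                genome_id=str(gid),
                detected=detected,
                domain=str(grp["domain"].iloc[0]),
                lineage=lineage,
            )
        )
    return genomes


def write_annotations(genomes: Iterable[GenomeAnnotation], path: str | Path) -> None:
    rows = []
    for g in genomes:
        lineage = ";".join(g.lineage)
        # a genome with no detections still gets one (blank-annotation) row
        for ident in sorted(g.detected) or [""]:
            rows.append((g.genome_id, g.domain, lineage, ident))
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------


def read_feature_table(
    counts_path: str | Path, taxonomy_path: str | Path, metadata_path: str | Path
) -> FeatureTable:
    """Read counts + taxonomy + metadata, reporting all violations together."""
    counts = pd.read_csv(counts_path, sep="\t", index_col="zotu_id")
    tax_raw = pd.read_csv(taxonomy_path, sep="\t", index_col="zotu_id")
    meta = pd.read_csv(metadata_path, sep="\t", index_col="sample_id")

    problems = []
    non_int = counts.columns[(counts % 1 != 0).any(axis=0)] if len(counts) else []
    if len(non_int):
        problems.append(f"non-integer counts in samples: {list(non_int)}")
    missing_meta = set(counts.columns) - set(meta.index)
    if missing_meta:
        problems.append(f"samples missing from metadata: {sorted(missing_meta)}")
    if "lineage" not in tax_raw.columns:
        problems.append("taxonomy table lacks 'lineage' column")
    if problems:
        raise ValidationError(problems)

    tax_ranks = RANKS[:-1]
    parsed = [parse_lineage(s, tax_ranks) for s in tax_raw["lineage"]]
    taxonomy = pd.DataFrame(parsed, columns=list(tax_ranks), index=tax_raw.index)
    taxonomy["zotu"] = taxonomy.index
    if "inoculated" in meta:
        meta["inoculated"] = meta["inoculated"].astype(bool)
    try:
        return FeatureTable(counts.astype(int), meta, taxonomy)
    except ValueError as exc:
        raise ValidationError([str(exc)]) from exc


def write_feature_table(table: FeatureTable, out_dir: str | Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out_dir / "counts.tsv",
        "taxonomy": out_dir / "taxonomy.tsv",
        "metadata": out_dir / "metadata.tsv",
    }
    table.counts.to_csv(paths["counts"], sep="\t", index_label="zotu_id")
    lineage = table.taxonomy[list(RANKS[:-1])].agg(";".join, axis=1)
    pd.DataFrame({"zotu_id": table.taxonomy.index, "lineage": lineage}).to_csv(
        paths["taxonomy"], sep="\t", index=False
    )
    table.sample_meta.to_csv(paths["metadata"], sep="\t", index_label="sample_id")
    return paths


# ---------------------------------------------------------------------------
# extraction series, plates, standards
# ---------------------------------------------------------------------------


def read_series(
    path: str | Path, geometry: ExtractionGeometry | None = None
) -> ExtractionSeries:
    frame = pd.read_csv(path, float_precision="round_trip")
    if "round" not in frame.columns or "aq_conc_nM" not in frame.columns:
        raise ValidationError(["series file needs columns: round, aq_conc_nM"])
    rounds = []
    for _, row in frame.iterrows():
        censored = bool(row.get("censored", False)) and str(row.get("censored")) not in (
            "0",
            "False",
            "false",
        )
        lod = float(row["lod_nM"]) if "lod_nM" in frame.columns and pd.notna(row.get("lod_nM")) else None
        rounds.append(
            ExtractionRound(
                n=int(row["round"]),
                aq_conc=None if censored else float(row["aq_conc_nM"]),
                censored=censored,
                lod=lod,
            )
        )
    try:
        return ExtractionSeries(tuple(rounds), geometry or ExtractionGeometry())
    except ValueError as exc:
        raise ValidationError([str(exc)]) from exc


def write_series(series: ExtractionSeries, path: str | Path) -> None:
    rows = [
        {
            "round": r.n,
            "aq_conc_nM": "" if r.censored else r.aq_conc,
            "censored": r.censored,
            "lod_nM": "" if r.lod is None else r.lod,
        }
        for r in series.rounds
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_plate(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = {"sample_id", "od600"} - set(frame.columns)
    if missing:
        raise ValidationError([f"plate file lacks columns: {sorted(missing)}"])
    return frame


def read_standards(path: str | Path) -> tuple[list[tuple[float, float]], list[float]]:
    """Split a calibration CSV into (conc, od) points and zero-conc blanks."""
    frame = pd.read_csv(path)
    missing = {"conc_nM", "od600"} - set(frame.columns)
    if missing:
        raise ValidationError([f"standards file lacks columns: {sorted(missing)}"])
    blanks = frame.loc[frame["conc_nM"] == 0, "od600"].tolist()
    pts_frame = frame[frame["conc_nM"] > 0].groupby("conc_nM")["od600"].agg(["mean", "std"])
    points = [
        (float(c), float(row["mean"]), 0.0 if pd.isna(row["std"]) else float(row["std"]))
        for c, row in pts_frame.iterrows()
    ]
    return points, blanks


# ---------------------------------------------------------------------------
# marker configuration
# ---------------------------------------------------------------------------


def read_marker_config(path: str | Path) -> MarkerConfig:
    data = yaml.safe_load(Path(path).read_text())
    try:
        return MarkerConfig(
            biosynthesis_markers=frozenset(data["biosynthesis_markers"]),
            dependent_markers={
                k: frozenset(v) for k, v in data["dependent_markers"].items()
            },
            independent_alternatives={
                k: frozenset(v) for k, v in data["independent_alternatives"].items()
            },
        )
    except KeyError as exc:
        raise ValidationError([f"marker config missing section {exc}"]) from exc


def write_marker_config(cfg: MarkerConfig, path: str | Path) -> None:
    data = {
        "biosynthesis_markers": sorted(cfg.biosynthesis_markers),
        "dependent_markers": {k: sorted(v) for k, v in cfg.dependent_markers.items()},
        "independent_alternatives": {
            k: sorted(v) for k, v in cfg.independent_alternatives.items()
        },
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
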