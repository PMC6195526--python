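"""Readers and writers for the standard formats the pipeline consumes.

Expression matrices come in as GCT 1.2 or plain TSV (first column = gene IDs),
gene sets as GMT, plate / confluence / mitotic measurements as CSV. Output
tables are written as TSV with a fixed float format so identical runs produce
byte-identical files.
"""

from __future__ import annotations

import io as _io
import logging
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import (
    CONDITIONS,
    MITOTIC_COLUMNS,
    PLATE_COLUMNS,
    ConfluenceTable,
    ExpressionCohort,
    GeneSet,
    MitoticCountTable,
    PlateSet,
    ROLE_NTC,
    ROLE_POS,
    ROLE_SAMPLE,
)

logger = logging.getLogger("sigscreen")

FLOAT_FORMAT = "%.10g"

_WELL_RE = re.compile(r"^([A-Pa-p])0*([1-9]\d?)$")

_ROLE_ALIASES = {
    "sample": ROLE_SAMPLE,
    "ntc": ROLE_NTC,
    "sintc": ROLE_NTC,
    "neg": ROLE_NTC,
    "pos": ROLE_POS,
    "sias": ROLE_POS,
}


def normalize_well(well: str) -> str:
    """Normalise a well address to zero-padded form, e.g. ``a1`` -> ``A01``."""
    m = _WELL_RE.match(str(well).strip())
    if not m:
        raise ValueError(f"invalid well address: {well!r}")
    return f"{m.group(1).upper()}{int(m.group(2)):02d}"


# ---------------------------------------------------------------------------
# expression / gene sets


def _read_annotations(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t")
    if "sample_id" not in ann.columns:
        raise ValueError("annotation table must have a 'sample_id' column")
    return ann.set_index("sample_id")


def read_expression(path, annotations=None, name: str | None = None) -> ExpressionCohort:
    """Read a genes x samples expression matrix from GCT 1.2 or TSV.

    ``annotations`` may be a path to a companion TSV with columns
    ``sample_id``, ``time``, ``event``, ``sample_type`` (and optionally
    ``subtype``).
    """
    path = Path(path)
    text = path.read_text()
    if text.startswith("#1.2"):
        lines = text.splitlines()
        n_genes, n_samples = (int(x) for x in lines[1].split("\t")[:2])
        body = "\n".join(lines[2:])
        df = pd.read_csv(_io.StringIO(body), sep="\t")
        df = df.set_index(df.columns[0])
        if "Description" in df.columns:
            df = df.drop(columns=["Description"])
        if df.shape != (n_genes, n_samples):
            raise ValueError(
                f"GCT header promises {(n_genes, n_samples)}, body has {df.shape}"
            )
    else:
        df = pd.read_csv(_io.StringIO(text), sep="\t")
        df = df.set_index(df.columns[0])
    dupes = df.index[df.index.duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate gene IDs in {path.name}: {sorted(map(str, dupes))}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(f"non-numeric expression value at gene {row!r}, sample {col!r}")
        df[col] = coerced
    ann = _read_annotations(annotations) if annotations is not None else None
    cohort = ExpressionCohort(values=df, annotations=ann, name=name or path.stem)
    logger.info("read_expression: %s shape=%s", path.name, cohort.values.shape)
    return cohort


def write_expression_tsv(cohort: ExpressionCohort, path) -> None:
    df = cohort.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def write_expression_gct(cohort: ExpressionCohort, path) -> None:
    df = cohort.values
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
        fh.write("Name\tDescription\t" + "\t".join(map(str, df.columns)) + "\n")
        for gene, row in df.iterrows():
            vals = "\t".join(FLOAT_FORMAT % v for v in row.to_numpy())
            fh.write(f"{gene}\tna\t{vals}\n")


def write_annotations(cohort: ExpressionCohort, path) -> None:
    if cohort.annotations is None:
        raise ValueError("cohort has no annotations")
    ann = cohort.annotations.copy()
    ann.index.name = "sample_id"
    ann.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_gmt(path) -> list[GeneSet]:
    """Read a GMT file: one gene set per line (name, description, members...)."""
    sets: list[GeneSet] = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}: line {i} has fewer than 3 tab-separated fields")
        genes = [g for g in fields[2:] if g]
        sets.append(GeneSet(name=fields[0], description=fields[1], genes=genes))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


def load_signature_geneset() -> GeneSet:
    """The packaged 48-gene aggressive prostate cancer signature."""
    from importlib.resources import files

    with files("sigscreen.data").joinpath("prostate48.gmt").open() as fh:
        line = fh.readline().rstrip("\n").split("\t")
    return GeneSet(name=line[0], description=line[1], genes=[g for g in line[2:] if g])


# ---------------------------------------------------------------------------
# plate / confluence / mitotic CSVs


def read_plate_csv(path) -> PlateSet:
    """Read per-well nuclei counts for a screen.

    Required columns: plate_id, well, cell_line, condition (DMSO/DCT), role
    (sample/NTC/POS, case-insensitive), gene, sirna_id, replicate,
    nuclei_count. Well addresses are normalised to zero-padded form.
    """
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad_count = df["nuclei_count"].isna()
    if bad_count.any():
        wells = df.loc[bad_count, ["plate_id", "well"]].astype(str).agg(":".join, axis=1)
        raise ValueError(f"{path}: missing nuclei_count at {wells.tolist()}")
    df["well"] = df["well"].map(normalize_well)
    df["role"] = df["role"].map(lambda r: _ROLE_ALIASES.get(str(r).lower(), str(r)))
    df["condition"] = df["condition"].str.upper()
    bad_cond = set(df["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise ValueError(f"{path}: unknown conditions {sorted(bad_cond)}")
    df["gene"] = df["gene"].fillna("")
    df["sirna_id"] = df["sirna_id"].fillna("")
    ps = PlateSet(wells=df)
    logger.info("read_plate_csv: %s wells=%d plates=%d", path, ps.n_wells, len(ps.plates()))
    return ps


def write_plate_csv(plates: PlateSet, path) -> None:
    plates.wells.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_confluence_csv(path, drug_addition_time: float) -> ConfluenceTable:
    df = pd.read_csv(path)
    return ConfluenceTable(measurements=df, drug_addition_time=drug_addition_time)


def write_confluence_csv(table: ConfluenceTable, path) -> None:
    table.measurements.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_mitotic_csv(path) -> MitoticCountTable:
    df = pd.read_csv(path)
    return MitoticCountTable(counts=df)


def write_mitotic_csv(table: MitoticCountTable, path) -> None:
    table.counts.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    """Write a result table as TSV with the package-wide float format."""
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Run-level constants of the screen and signature pipeline.

    ``ec30_doses`` holds the per-line docetaxel dose (nM) producing 30%
    growth inhibition, the screen's design point; ``hit_k_sd`` the cutoff
    multiplier in the mean + k*SD sequence rule; ``ci_quantile`` the empirical
    quantile of the combination-index pool used to flag synergy.
    """

    seed: int = 0
    cell_lines: list = field(default_factory=lambda: ["LNCaP", "PC3", "DU145"])
    ec30_doses: dict = field(
        default_factory=lambda: {"LNCaP": 1.80, "PC3": 1.36, "DU145": 3.28}
    )
    hit_k_sd: float = 2.0
    window_k_sd: float = 1.0
    min_sequences: int = 2
    min_cell_lines: int = 2
    ci_quantile: float = 0.05
    ssgsea_alpha: float = 0.25
    kmeans_k: int = 3
    zprime_threshold: float = 0.5
    output_dir: str = "sigscreen_out"

    def __post_init__(self) -> None:
        if self.hit_k_sd <= 0 or self.window_k_sd <= 0:
            raise ValueError("cutoff multipliers must be strictly positive")
        if not (0 < self.ci_quantile < 1):
            raise ValueError("ci_quantile must lie in (0, 1)")
        if self.ssgsea_alpha < 0:
            raise ValueError("ssgsea_alpha must be non-negative")
        if self.kmeans_k < 1:
            raise ValueError("kmeans_k must be >= 1")
        if self.min_sequences < 1 or self.min_cell_lines < 1:
            raise ValueError("min_sequences and min_cell_lines must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    """Load a RunConfig from a flat YAML file; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**raw)
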