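"""Core data containers shared across pipeline stages.

All tabular data are held as pandas DataFrames inside light dataclasses that
validate the invariants each downstream stage relies on (unique gene IDs,
non-negative counts, controls present on every plate, binary event flags).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("sigscreen")

ROLE_SAMPLE = "sample"
ROLE_NTC = "NTC"
ROLE_POS = "POS"
ROLES = (ROLE_SAMPLE, ROLE_NTC, ROLE_POS)

COND_VEHICLE = "DMSO"
COND_DRUG = "DCT"
CONDITIONS = (COND_VEHICLE, COND_DRUG)

PLATE_COLUMNS = [
    "plate_id",
    "well",
    "cell_line",
    "condition",
    "role",
    "gene",
    "sirna_id",
    "replicate",
    "nuclei_count",
]

CONFLUENCE_COLUMNS = [
    "experiment",
    "well",
    "cell_line",
    "condition",
    "time_h",
    "confluence",
]

MITOTIC_COLUMNS = [
    "experiment",
    "well",
    "sirna",
    "drug",
    "metaphase_count",
    "postmeta_count",
]


@dataclass
class ExpressionCohort:
    """A genes x samples expression matrix with optional per-sample annotation.

    ``values`` is a DataFrame indexed by gene ID with one column per sample,
    assumed log-scale or at least rank-comparable within a sample.
    ``annotations`` (optional) is indexed by sample ID with columns drawn from
    ``time`` (non-negative follow-up), ``event`` (0/1), ``sample_type`` and
    ``subtype``.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame | None = None
    name: str = "cohort"

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            raise TypeError("values must be a pandas DataFrame (genes x samples)")
        dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
        if dupes:
            raise ValueError(f"duplicate gene IDs: {sorted(map(str, dupes))}")
        if not all(np.issubdtype(dt, np.number) for dt in self.values.dtypes):
            bad = [c for c in self.values.columns
                   if not np.issubdtype(self.values[c].dtype, np.number)]
            raise ValueError(f"non-numeric expression columns: {bad}")
        all_missing = self.values.index[self.values.isna().all(axis=1)]
        if len(all_missing):
            logger.warning(
                "%s: dropping %d genes with all-missing values", self.name, len(all_missing)
            )
            self.values = self.values.drop(index=all_missing)
        if self.annotations is not None:
            ann = self.annotations.reindex(self.values.columns)
            if "time" in ann.columns:
                t = ann["time"].dropna()
                if (t < 0).any():
                    raise ValueError("survival times must be >= 0")
            if "event" in ann.columns:
                ev = ann["event"].dropna()
                if not set(np.unique(ev)).issubset({0, 1}):
                    raise ValueError("event indicator must be binary 0/1")
            self.annotations = ann

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def set_mean(self, genes) -> pd.Series:
        """Per-sample mean expression over the given genes (missing genes dropped)."""
        present = [g for g in genes if g in self.values.index]
        if not present:
            raise ValueError("none of the requested genes are present in the cohort")
        return self.values.loc[present].mean(axis=0)


@dataclass
class GeneSet:
    """A named gene set (GMT line); member order is preserved."""

    name: str
    description: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


@dataclass
class PlateSet:
    """All wells of a screen: one row per measured well.

    Columns follow :data:`PLATE_COLUMNS`. Every (plate, condition) group must
    contain at least one non-targeting control well, since %GI normalisation is
    defined against the NTC median of the same plate and arm.
    """

    wells: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PLATE_COLUMNS if c not in self.wells.columns]
        if missing:
            raise ValueError(f"plate table missing columns: {missing}")
        w = self.wells.copy()
        counts = w["nuclei_count"]
        if counts.isna().any():
            bad = w.loc[counts.isna(), ["plate_id", "well"]].astype(str).agg(":".join, axis=1)
            raise ValueError(f"missing nuclei_count at wells: {bad.tolist()}")
        if (counts < 0).any():
            bad = w.loc[counts < 0, ["plate_id", "well"]].astype(str).agg(":".join, axis=1)
            raise ValueError(f"negative nuclei_count at wells: {bad.tolist()}")
        bad_roles = set(w["role"].unique()) - set(ROLES)
        if bad_roles:
            raise ValueError(f"unknown roles: {sorted(bad_roles)}")
        bad_cond = set(w["condition"].unique()) - set(CONDITIONS)
        if bad_cond:
            raise ValueError(f"unknown conditions: {sorted(bad_cond)}")
        ntc_per = w.groupby(["plate_id", "condition"], observed=True)["role"].apply(
            lambda r: (r == ROLE_NTC).sum()
        )
        no_ntc = ntc_per[ntc_per == 0]
        if len(no_ntc):
            raise ValueError(
                "plates without NTC wells (normalisation impossible): "
                f"{no_ntc.index.tolist()}"
            )
        self.wells = w

    @property
    def n_wells(self) -> int:
        return len(self.wells)

    def plates(self) -> list[str]:
        return sorted(self.wells["plate_id"].unique())


@dataclass
class ConfluenceTable:
    """Time-stamped % confluence measurements, long format, plus the drug-addition time."""

    measurements: pd.DataFrame
    drug_addition_time: float

    def __post_init__(self) -> None:
        missing = [c for c in CONFLUENCE_COLUMNS if c not in self.measurements.columns]
        if missing:
            raise ValueError(f"confluence table missing columns: {missing}")


@dataclass
class MitoticCountTable:
    """Per-well metaphase and post-metaphase counts with condition labels."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MITOTIC_COLUMNS if c not in self.counts.columns]
        if missing:
            raise ValueError(f"mitotic count table missing columns: {missing}")
        for col in ("metaphase_count", "postmeta_count"):
            c = self.counts[col]
            if c.isna().any() or (c < 0).any():
                raise ValueError(f"{col} must be non-negative integers")
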