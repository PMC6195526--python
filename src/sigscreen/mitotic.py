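"""Post-metaphase / metaphase ratio analysis of immunofluorescence counts.

The per-well ratio of post-metaphase to metaphase mitotic cells proxies
progression through the metaphase-anaphase transition under mitotic insult.
Averaging is two-level — wells to an experiment mean, experiments to a grand
mean with SEM across experiments — matching how replicate imaging
experiments are summarised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import MitoticCountTable

logger = logging.getLogger("sigscreen")

COND = ["sirna", "drug"]


def phase_ratio(counts: MitoticCountTable) -> pd.DataFrame:
    """Per-well post-metaphase/metaphase ratio; zero-metaphase wells excluded."""
    df = counts.counts.copy()
    undefined = df["metaphase_count"] == 0
    if undefined.any():
        logger.info(
            "phase_ratio: excluding %d wells with zero metaphase cells: %s",
            int(undefined.sum()), df.loc[undefined, "well"].tolist(),
        )
    df = df[~undefined].copy()
    df["ratio"] = df["postmeta_count"] / df["metaphase_count"]
    return df


def condition_summary(counts: MitoticCountTable) -> pd.DataFrame:
    """Two-level average: wells -> experiment mean ratio -> grand mean +/- SEM.

    Conditions with no valid well in any experiment are omitted with a
    warning; a single-experiment condition reports SEM as missing.
    """
    ratios = phase_ratio(counts)
    if ratios.empty:
        raise ValueError("no wells with defined ratios")
    all_conditions = counts.counts[COND].drop_duplicates()
    exp_means = (
        ratios.groupby(COND + ["experiment"], sort=True)["ratio"].mean().reset_index()
    )
    rows = []
    for _, cond in all_conditions.iterrows():
        sel = exp_means[(exp_means["sirna"] == cond["sirna"]) & (exp_means["drug"] == cond["drug"])]
        if sel.empty:
            logger.warning("condition_summary: condition %s omitted (no valid wells)",
                           tuple(cond))
            continue
        vals = sel["ratio"].to_numpy(dtype=float)
        rows.append(
            {
                "sirna": cond["sirna"],
                "drug": cond["drug"],
                "mean_ratio": vals.mean(),
                "sem_ratio": vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan,
                "n_experiments": vals.size,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class DctEffect:
    sirna: str
    fold_change: float
    t_statistic: float | None
    p_value: float | None
    n_experiments: int


def dct_effect(
    counts: MitoticCountTable,
    drug_condition: str = "DCT",
    vehicle_condition: str = "DMSO",
    log_ratios: bool = False,
) -> pd.DataFrame:
    """Fold change of the phase ratio under drug vs vehicle per siRNA condition.

    The fold change is the ratio of experiment-level mean ratios (grand mean
    drug / grand mean vehicle); significance is a two-sided paired-design
    t-test across experiment-level ratios (on log ratios when
    ``log_ratios``). With < 2 experiments the fold change is reported
    without a p-value.
    """
    ratios = phase_ratio(counts)
    exp_means = ratios.groupby(COND + ["experiment"], sort=True)["ratio"].mean().reset_index()
    rows = []
    for sirna, grp in exp_means.groupby("sirna", sort=True):
        d = grp[grp["drug"] == drug_condition].set_index("experiment")["ratio"]
        v = grp[grp["drug"] == vehicle_condition].set_index("experiment")["ratio"]
        if d.empty or v.empty:
            raise ValueError(f"siRNA condition {sirna}: both drug conditions required")
        fc = float(d.mean() / v.mean())
        common = d.index.intersection(v.index)
        t = p = None
        if len(common) >= 2:
            a, b = d.loc[common], v.loc[common]
            if log_ratios:
                a, b = np.log(a), np.log(b)
            t, p = stats.ttest_rel(a, b)
            t, p = float(t), float(p)
        rows.append(
            {
                "sirna": sirna,
                "fold_change": fc,
                "t_statistic": t,
                "p_value": p,
                "n_experiments": len(common),
            }
        )
    return pd.DataFrame(rows)
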