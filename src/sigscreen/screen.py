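"""Arrayed siRNA screen analysis.

Plate QC (Z-prime), per-well %GI against the NTC median of the same plate and
arm, replicate aggregation, deconvoluted hit calling (a gene needs >= 2
significant sequences in >= 2 cell lines), the drug-minus-vehicle window of
efficacy, and Bliss-independence combination indices with an empirical
quantile significance rule.

Conventions adopted where the source methods leave the formula open:

* Z' = 1 - 3 (sd_pos + sd_neg) / |mu_pos - mu_neg| on raw counts.
* CI = (f_A + f_B - f_A f_B) / f_AB, so CI = 1 at Bliss independence and
  CI < 1 means synergy.
* For Bliss, all three fractional inhibitions are referenced to the NTC
  median of the vehicle (DMSO) arm — the untreated baseline the model
  requires — whereas display %GI uses the arm-matched NTC. Negative GI is
  clipped to 0 only when converted to Bliss fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import COND_DRUG, COND_VEHICLE, PlateSet, ROLE_NTC, ROLE_POS, ROLE_SAMPLE

logger = logging.getLogger("sigscreen")

STRATUM = ["cell_line", "gene", "sirna_id"]


# ---------------------------------------------------------------------------
# plate QC


@dataclass
class PlateQC:
    plate_id: str
    z_prime: float
    mu_neg: float
    sd_neg: float
    mu_pos: float
    sd_pos: float
    passed: bool


def plate_zprime(wells: pd.DataFrame, threshold: float = 0.5) -> PlateQC:
    """Z-prime of one plate from its NTC (negative) and POS control wells."""
    neg = wells.loc[wells["role"] == ROLE_NTC, "nuclei_count"].to_numpy(dtype=float)
    pos = wells.loc[wells["role"] == ROLE_POS, "nuclei_count"].to_numpy(dtype=float)
    if neg.size < 2 or pos.size < 2:
        raise ValueError("Z-prime needs >= 2 NTC and >= 2 POS wells")
    mu_n, sd_n = neg.mean(), neg.std(ddof=1)
    mu_p, sd_p = pos.mean(), pos.std(ddof=1)
    if mu_p == mu_n:
        raise ValueError("control separation zero: mu_pos == mu_neg")
    z = 1.0 - 3.0 * (sd_p + sd_n) / abs(mu_p - mu_n)
    plate_id = str(wells["plate_id"].iloc[0]) if "plate_id" in wells else ""
    return PlateQC(plate_id, float(z), float(mu_n), float(sd_n),
                   float(mu_p), float(sd_p), bool(z > threshold))


def screen_qc(plates: PlateSet, threshold: float = 0.5) -> pd.DataFrame:
    """Z-prime table for every plate of a screen."""
    rows = []
    for pid, grp in plates.wells.groupby("plate_id", sort=True):
        qc = plate_zprime(grp, threshold=threshold)
        rows.append(vars(qc))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# %GI and aggregation


def percent_gi(plates: PlateSet) -> pd.DataFrame:
    """%GI per sample well: (median(NTC) - count) / median(NTC) * 100.

    The NTC median is taken from the same plate and the same arm as the
    sample well, so drug-arm samples are measured relative to NTC-in-drug.
    """
    w = plates.wells
    rows = []
    for (pid, cond), grp in w.groupby(["plate_id", "condition"], sort=True):
        ntc = grp.loc[grp["role"] == ROLE_NTC, "nuclei_count"]
        if ntc.empty:
            raise ValueError(f"plate {pid} arm {cond}: no NTC wells")
        med = float(ntc.median())
        if med <= 0:
            raise ValueError(f"plate {pid} arm {cond}: NTC median is {med}")
        samp = grp[grp["role"] == ROLE_SAMPLE].copy()
        samp["gi_percent"] = (med - samp["nuclei_count"]) / med * 100.0
        samp["ntc_median"] = med
        rows.append(samp)
    out = pd.concat(rows, ignore_index=True)
    logger.info("percent_gi: %d sample wells normalised", len(out))
    return out


def aggregate_gi(gi_wells: pd.DataFrame) -> pd.DataFrame:
    """Mean %GI over replicate experiments per (cell line, gene, sequence, condition)."""
    g = gi_wells.groupby(STRATUM + ["condition"], sort=True)["gi_percent"]
    out = g.agg(gi_percent="mean", n_replicates="count",
                gi_replicates=lambda s: list(s)).reset_index()
    return out


# ---------------------------------------------------------------------------
# hit calling


def _call_hits(
    values: pd.DataFrame,
    value_col: str,
    k_sd: float,
    min_sequences: int,
    min_cell_lines: int,
) -> pd.DataFrame:
    """Shared mean + k*SD rule: per-line cutoff over all gene x sequence values."""
    lines = values["cell_line"].unique()
    if len(lines) < min_cell_lines:
        raise ValueError(
            f"table covers {len(lines)} cell lines, needs >= {min_cell_lines}"
        )
    cutoffs = {}
    flagged = values.copy()
    flagged["significant"] = False
    for line, grp in values.groupby("cell_line"):
        v = grp[value_col].to_numpy(dtype=float)
        cut = v.mean() + k_sd * v.std(ddof=1)
        cutoffs[line] = cut
        flagged.loc[grp.index, "significant"] = grp[value_col] >= cut
    per_line = (
        flagged.groupby(["gene", "cell_line"])["significant"].sum().unstack(fill_value=0)
    )
    line_sig = per_line >= min_sequences
    calls = pd.DataFrame(
        {
            "n_lines_significant": line_sig.sum(axis=1),
            "called": line_sig.sum(axis=1) >= min_cell_lines,
        }
    )
    for line in per_line.columns:
        calls[f"n_sig_sequences_{line}"] = per_line[line]
    calls = calls.reset_index()
    calls.attrs["cutoffs"] = cutoffs
    calls.attrs["k_sd"] = k_sd
    return calls


def call_hits_growth(
    agg_gi: pd.DataFrame,
    k_sd: float = 2.0,
    min_sequences: int = 2,
    min_cell_lines: int = 2,
) -> pd.DataFrame:
    """Growth-arm hit calling on replicate-mean %GI (vehicle arm).

    Per line the cutoff is mean + k_sd * SD over all gene x sequence GI
    values; a sequence is significant at GI >= cutoff, a gene significant in
    a line with >= ``min_sequences`` significant sequences, and called when
    significant in >= ``min_cell_lines`` lines.
    """
    arm = agg_gi[agg_gi["condition"] == COND_VEHICLE] if "condition" in agg_gi else agg_gi
    if arm.empty:
        raise ValueError("no vehicle-arm GI values")
    calls = _call_hits(arm, "gi_percent", k_sd, min_sequences, min_cell_lines)
    calls.insert(1, "arm", "growth")
    return calls


def compute_window(agg_gi: pd.DataFrame) -> pd.DataFrame:
    """Window of efficacy: GI(drug) - GI(vehicle) per (line, gene, sequence)."""
    wide = agg_gi.pivot_table(
        index=STRATUM, columns="condition", values="gi_percent", aggfunc="first"
    )
    missing = wide.index[wide.isna().any(axis=1)]
    if len(missing):
        logger.warning("compute_window: %d strata missing one arm, skipped", len(missing))
        wide = wide.drop(index=missing)
    if COND_DRUG not in wide.columns or COND_VEHICLE not in wide.columns:
        raise ValueError("both DMSO and DCT arms are required")
    out = wide.reset_index()
    out["window"] = out[COND_DRUG] - out[COND_VEHICLE]
    out = out.rename(columns={COND_DRUG: "gi_dct", COND_VEHICLE: "gi_dmso"})
    stats = out.groupby("cell_line")["window"].agg(["mean", "std"])
    out.attrs["per_line_stats"] = stats.to_dict("index")
    return out


def call_hits_window(
    windows: pd.DataFrame,
    k_sd: float = 1.0,
    min_sequences: int = 2,
    min_cell_lines: int = 2,
) -> pd.DataFrame:
    """Synergy-arm hit calling on windows with per-line mean + k*SD cutoffs."""
    calls = _call_hits(windows, "window", k_sd, min_sequences, min_cell_lines)
    calls.insert(1, "arm", "synergy")
    return calls


# ---------------------------------------------------------------------------
# Bliss combination index


def bliss_ci(f_a, f_b, f_ab):
    """Bliss combination index: expected over observed fractional inhibition.

    CI = (f_A + f_B - f_A f_B) / f_AB; 1 at independence, < 1 synergy.
    f_AB <= 0 yields +inf (no observed combined effect).
    """
    f_a = np.asarray(f_a, dtype=float)
    f_b = np.asarray(f_b, dtype=float)
    f_ab = np.asarray(f_ab, dtype=float)
    if np.any((f_a < 0) | (f_a > 1)) or np.any((f_b < 0) | (f_b > 1)):
        raise ValueError("f_A and f_B must lie in [0, 1]")
    expected = f_a + f_b - f_a * f_b
    with np.errstate(divide="ignore", invalid="ignore"):
        ci = np.where(f_ab > 0, expected / np.where(f_ab > 0, f_ab, 1.0), np.inf)
    return ci if ci.ndim else float(ci)


def screen_bliss(plates: PlateSet) -> pd.DataFrame:
    """Per-experiment Bliss fractions and CI for every (line, gene, sequence).

    For each replicate experiment: f_A is the knockdown-alone inhibition
    (vehicle-arm well vs its plate's vehicle NTC median), f_B the drug-alone
    inhibition (drug-arm NTC median vs the vehicle NTC median), f_AB the
    combined inhibition (drug-arm well vs the vehicle NTC median). All
    fractions are clipped to [0, 1]; clipping is logged.
    """
    w = plates.wells
    ntc_med = (
        w[w["role"] == ROLE_NTC]
        .groupby(["plate_id", "condition"])["nuclei_count"]
        .median()
    )
    samp = w[w["role"] == ROLE_SAMPLE]
    key = STRATUM + ["replicate"]
    veh = samp[samp["condition"] == COND_VEHICLE].set_index(key)
    drug = samp[samp["condition"] == COND_DRUG].set_index(key)
    common = veh.index.intersection(drug.index)
    if common.empty:
        raise ValueError("no strata measured in both arms")

    v = veh.loc[common]
    d = drug.loc[common]
    base = ntc_med.loc[
        list(zip(v["plate_id"], [COND_VEHICLE] * len(v)))
    ].to_numpy(dtype=float)
    ntc_dct = ntc_med.loc[
        list(zip(d["plate_id"], [COND_DRUG] * len(d)))
    ].to_numpy(dtype=float)

    raw_fa = 1.0 - v["nuclei_count"].to_numpy(dtype=float) / base
    raw_fb = 1.0 - ntc_dct / base
    raw_fab = 1.0 - d["nuclei_count"].to_numpy(dtype=float) / base
    n_clip = int(((raw_fa < 0) | (raw_fb < 0) | (raw_fab < 0)).sum())
    if n_clip:
        logger.info("screen_bliss: %d negative fractions clipped to 0", n_clip)
    f_a = np.clip(raw_fa, 0.0, 1.0)
    f_b = np.clip(raw_fb, 0.0, 1.0)
    f_ab = np.clip(raw_fab, 0.0, 1.0)

    out = pd.DataFrame(index=common).reset_index()
    out["f_a"] = f_a
    out["f_b"] = f_b
    out["f_ab"] = f_ab
    out["ci"] = bliss_ci(f_a, f_b, f_ab)
    return out


def aggregate_bliss(records: pd.DataFrame) -> pd.DataFrame:
    """Per-stratum mean CI and standard error across replicate experiments.

    Strata with no finite CI (all f_AB <= 0) get mean_ci = NaN and are flagged
    excluded; they do not enter the significance pool.
    """

    def _agg(g: pd.DataFrame) -> pd.Series:
        finite = g.loc[np.isfinite(g["ci"]), "ci"]
        n = len(finite)
        return pd.Series(
            {
                "mean_ci": finite.mean() if n else np.nan,
                "stderr_ci": finite.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                "n_finite": n,
                "excluded": n == 0,
            }
        )

    out = records.groupby(STRATUM, sort=True).apply(_agg, include_groups=False).reset_index()
    n_excl = int(out["excluded"].sum())
    if n_excl:
        logger.warning("aggregate_bliss: %d strata with no finite CI excluded", n_excl)
    return out


def ci_significance(stratum_ci: pd.DataFrame, q: float = 0.05) -> pd.DataFrame:
    """Flag synergistic strata against the per-line empirical CI quantile.

    Within each cell line the pool is all finite per-stratum mean CIs; the
    threshold is the empirical ``q``-quantile (linear interpolation) and a
    stratum is flagged when its mean CI <= threshold.
    """
    out = stratum_ci.copy()
    out["ci_threshold"] = np.nan
    out["flagged"] = False
    thresholds = {}
    for line, grp in out.groupby("cell_line"):
        pool = grp.loc[np.isfinite(grp["mean_ci"]), "mean_ci"].to_numpy()
        if pool.size < 20:
            raise ValueError(
                f"cell line {line}: insufficient distribution "
                f"({pool.size} finite CI values, need >= 20)"
            )
        thr = float(np.quantile(pool, q))
        thresholds[line] = thr
        out.loc[grp.index, "ci_threshold"] = thr
        out.loc[grp.index, "flagged"] = grp["mean_ci"] <= thr
        if np.allclose(pool, pool[0]):
            logger.warning("ci_significance: %s CI pool degenerate (all equal)", line)
    out.attrs["thresholds"] = thresholds
    return out


def call_hits_ci(flagged: pd.DataFrame, min_sequences: int = 2) -> pd.DataFrame:
    """Gene-level synergy call per line: >= min_sequences flagged sequences."""
    per = (
        flagged.groupby(["cell_line", "gene"])["flagged"].sum().reset_index(
            name="n_flagged_sequences"
        )
    )
    per["called"] = per["n_flagged_sequences"] >= min_sequences
    return per
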