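"""Confluence growth-curve analysis and dose-response estimation.

Curves are normalised by the confluence at drug-addition time (cancelling
seeding-density variation), expressed as drug-over-vehicle ratios per
experiment, and compared by trapezoidal AUC with a two-sample t-test.
EC_x doses come from a four-parameter logistic fit on log dose, with a
monotone-interpolation fallback and explicit out-of-range bounds when the
response never reaches x% within the tested dose range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

from .types import ConfluenceTable

logger = logging.getLogger("sigscreen")


# ---------------------------------------------------------------------------
# normalisation and relative growth


def normalize_confluence(times, values, drug_addition_time, scan_interval=None):
    """Divide a confluence series by its value at (nearest-to) drug addition.

    The anchor is the scan closest to ``drug_addition_time``; if
    ``scan_interval`` is given, the nearest scan must lie within half an
    interval of the anchor time.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    i = int(np.argmin(np.abs(times - drug_addition_time)))
    if scan_interval is not None and abs(times[i] - drug_addition_time) > scan_interval / 2:
        raise ValueError("no scan within half a scan interval of drug addition")
    anchor = values[i]
    if anchor <= 0:
        raise ValueError(f"anchor confluence {anchor} at t={times[i]} is not positive")
    return values / anchor


@dataclass
class RelativeGrowthCurve:
    times: np.ndarray
    mean_ratio: np.ndarray
    sem_ratio: np.ndarray
    per_experiment: pd.DataFrame  # experiment x time ratio values
    drug_addition_time: float


def _experiment_curve(df: pd.DataFrame, drug_addition_time: float) -> tuple[np.ndarray, np.ndarray]:
    """Replicate-averaged, normalised curve for one experiment/condition."""
    mean = df.groupby("time_h", sort=True)["confluence"].mean()
    times = mean.index.to_numpy(dtype=float)
    norm = normalize_confluence(times, mean.to_numpy(), drug_addition_time)
    return times, norm


def relative_growth(
    table: ConfluenceTable, drug_condition: str = "DCT", vehicle_condition: str = "DMSO"
) -> RelativeGrowthCurve:
    """Drug-over-vehicle ratio of normalised growth curves, per experiment.

    Vehicle curves are linearly interpolated onto the drug timestamps when
    scan grids differ; the ratio is 1 at drug-addition time by construction.
    """
    df = table.measurements
    ta = table.drug_addition_time
    ratios = {}
    ref_times = None
    for exp, grp in df.groupby("experiment", sort=True):
        d = grp[grp["condition"] == drug_condition]
        v = grp[grp["condition"] == vehicle_condition]
        if d.empty or v.empty:
            raise ValueError(f"experiment {exp}: missing {drug_condition} or {vehicle_condition}")
        td, cd = _experiment_curve(d, ta)
        tv, cv = _experiment_curve(v, ta)
        if td[0] > tv[-1] or tv[0] > td[-1]:
            raise ValueError(f"experiment {exp}: non-overlapping time ranges")
        mask = (td >= tv[0]) & (td <= tv[-1])
        td = td[mask]
        cv_on_d = np.interp(td, tv, cv)
        ratios[exp] = pd.Series(cd[mask] / cv_on_d, index=td)
        if ref_times is None:
            ref_times = td
    per_exp = pd.DataFrame(ratios).T
    per_exp.index.name = "experiment"
    mean = per_exp.mean(axis=0).to_numpy()
    n = per_exp.shape[0]
    sem = per_exp.std(axis=0, ddof=1).to_numpy() / np.sqrt(n) if n > 1 else np.full(mean.shape, np.nan)
    return RelativeGrowthCurve(
        times=per_exp.columns.to_numpy(dtype=float),
        mean_ratio=mean,
        sem_ratio=sem,
        per_experiment=per_exp,
        drug_addition_time=ta,
    )


# ---------------------------------------------------------------------------
# AUC comparison


def auc(times, values, window: tuple | None = None) -> float:
    """Trapezoidal area under a curve over ``window`` (default: full range).

    Window endpoints falling between scans are linearly interpolated, which
    keeps the integral additive over adjacent windows and exact for
    piecewise-linear curves.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if window is None:
        t0, t1 = times[0], times[-1]
    else:
        t0, t1 = window
    if t0 < times[0] - 1e-12 or t1 > times[-1] + 1e-12 or t1 <= t0:
        raise ValueError(f"window ({t0}, {t1}) outside data range ({times[0]}, {times[-1]})")
    inner = times[(times > t0) & (times < t1)]
    grid = np.concatenate(([t0], inner, [t1]))
    vals = np.interp(grid, times, values)
    if grid.size < 2:
        raise ValueError("need >= 2 points in window")
    return float(np.trapezoid(vals, grid))


@dataclass
class AUCComparison:
    auc_a: list
    auc_b: list
    t_statistic: float
    p_value: float
    window: tuple


def compare_auc(
    curves_a: pd.DataFrame,
    curves_b: pd.DataFrame,
    window: tuple | None = None,
    welch: bool = True,
) -> AUCComparison:
    """Two-sided t-test on per-experiment AUCs of two groups of curves.

    Inputs are experiment x time DataFrames (as produced by
    :func:`relative_growth`); the AUC window defaults to the common time
    range of both groups.
    """
    if len(curves_a) < 2 or len(curves_b) < 2:
        raise ValueError("need >= 2 curves per group")
    ta = curves_a.columns.to_numpy(dtype=float)
    tb = curves_b.columns.to_numpy(dtype=float)
    if window is None:
        window = (max(ta[0], tb[0]), min(ta[-1], tb[-1]))
    auc_a = [auc(ta, row.to_numpy(dtype=float), window) for _, row in curves_a.iterrows()]
    auc_b = [auc(tb, row.to_numpy(dtype=float), window) for _, row in curves_b.iterrows()]
    t, p = stats.ttest_ind(auc_a, auc_b, equal_var=not welch)
    return AUCComparison(auc_a, auc_b, float(t), float(p), window)


# ---------------------------------------------------------------------------
# dose-response EC_x


def four_param_logistic(dose, bottom, top, ec50, hill):
    """4PL response (fractional inhibition) as a function of dose."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ec50 / dose) ** hill)


@dataclass
class ECxResult:
    x: float
    dose: float | None  # estimated dose, None when out of range
    bound: str | None  # ">" (above max dose) or "<" (below min dose)
    bound_dose: float | None
    method: str  # "4pl" or "interpolation"
    params: dict = field(default_factory=dict)

    def __str__(self) -> str:
        if self.bound:
            return f"EC{self.x:g} {self.bound} {self.bound_dose:g} nM"
        return f"EC{self.x:g} = {self.dose:.4g} nM"


def estimate_ecx(doses, responses, x: float) -> ECxResult:
    """Dose at which the fitted response reaches x% inhibition.

    Fits a four-parameter logistic on dose (hill slope on log dose); when the
    fit fails, falls back to monotone piecewise-linear interpolation of the
    response against log dose. A target level outside the fitted range within
    the tested doses is reported as a bound (e.g. EC40 > max dose).
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.size < 4:
        raise ValueError("need >= 4 dose levels")
    if np.any(doses <= 0):
        raise ValueError("doses must be strictly positive")
    if x <= 0 or x >= 100:
        raise ValueError("degenerate level: x must lie in (0, 100)")
    order = np.argsort(doses)
    doses, responses = doses[order], responses[order]
    y = x / 100.0

    params: dict = {}
    method = "4pl"
    try:
        p0 = (
            float(responses.min()),
            float(responses.max()),
            float(np.exp(np.mean(np.log(doses)))),
            1.0,
        )
        bounds = ([-0.5, 0.0, doses.min() / 1e3, 0.1], [0.5, 1.5, doses.max() * 1e3, 10.0])
        popt, _ = curve_fit(four_param_logistic, doses, responses, p0=p0,
                            bounds=bounds, maxfev=10000)
        bottom, top, ec50, hill = popt
        params = {"bottom": bottom, "top": top, "ec50": ec50, "hill": hill}
        pred = lambda d: four_param_logistic(d, *popt)  # noqa: E731
        if not (bottom < y < top):
            pred_range = (pred(doses.min()), pred(doses.max()))
        else:
            dose_x = float(ec50 * ((y - bottom) / (top - y)) ** (1.0 / hill))
            if doses.min() <= dose_x <= doses.max():
                return ECxResult(x, dose_x, None, None, method, params)
            pred_range = (pred(doses.min()), pred(doses.max()))
    except RuntimeError:
        method = "interpolation"
        mono = np.maximum.accumulate(responses)
        if y > mono[-1]:
            return ECxResult(x, None, ">", float(doses.max()), method)
        if y < mono[0]:
            return ECxResult(x, None, "<", float(doses.min()), method)
        dose_x = float(np.exp(np.interp(y, mono, np.log(doses))))
        return ECxResult(x, dose_x, None, None, method)

    lo, hi = pred_range
    if y > max(lo, hi):
        return ECxResult(x, None, ">", float(doses.max()), method, params)
    return ECxResult(x, None, "<", float(doses.min()), method, params)
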