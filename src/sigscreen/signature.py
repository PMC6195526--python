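"""Prognostic gene-signature pipeline.

Derives a gene list from multi-cohort differential expression, scores every
sample with single-sample GSEA (ssGSEA), clusters the scores into prognostic
groups (k-means, labelled high / intermediate / low by descending cluster
mean), and runs the survival, correlation and ANOVA analyses used to
characterise the signature.

ssGSEA here is the rank-weighted running-sum statistic: for one sample, genes
are ranked by expression (ties get the average rank); walking down the list
from the most expressed gene, the score accumulates the difference between
the weighted in-set ECDF (set-member ranks weighted by rank^alpha, normalised
to 1) and the uniform ECDF over non-members.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .types import ExpressionCohort, GeneSet

logger = logging.getLogger("sigscreen")


# ---------------------------------------------------------------------------
# gene-list derivation


def differential_selection(
    cohorts: list[ExpressionCohort],
    case_label: str = "aggressive",
    control_label: str = "normal-like",
    fc_cutoff: float = 1.0,
    fdr_cutoff: float = 0.05,
    min_sets: int = 2,
    return_details: bool = False,
):
    """Select genes differentially expressed in >= ``min_sets`` cohorts.

    Per cohort and gene: a two-sided Wilcoxon rank-sum test between the two
    subtype groups plus the difference of group medians (log-scale data, so a
    log fold change); p-values are Benjamini-Hochberg adjusted within cohort.
    A gene is selected iff FDR < ``fdr_cutoff`` and \\|logFC\\| > ``fc_cutoff``
    in at least ``min_sets`` cohorts; genes absent from a cohort count as
    non-significant there.
    """
    if len(cohorts) < min_sets:
        raise ValueError(f"need at least {min_sets} cohorts")
    all_genes: set = set()
    per_cohort = []
    for cohort in cohorts:
        if cohort.annotations is None or "subtype" not in cohort.annotations.columns:
            raise ValueError(f"cohort {cohort.name} lacks subtype labels")
        labels = cohort.annotations["subtype"]
        case = cohort.values.loc[:, (labels == case_label).to_numpy()]
        ctrl = cohort.values.loc[:, (labels == control_label).to_numpy()]
        if case.shape[1] < 3 or ctrl.shape[1] < 3:
            raise ValueError(
                f"cohort {cohort.name}: each subtype group needs >= 3 samples"
            )
        stat = stats.ranksums(case, ctrl, axis=1)
        logfc = case.median(axis=1) - ctrl.median(axis=1)
        fdr = multipletests(stat.pvalue, method="fdr_bh")[1]
        res = pd.DataFrame(
            {"logfc": logfc, "pvalue": stat.pvalue, "fdr": fdr}, index=cohort.values.index
        )
        res["significant"] = (res["fdr"] < fdr_cutoff) & (res["logfc"].abs() > fc_cutoff)
        per_cohort.append(res)
        all_genes |= set(cohort.values.index)
    common = set.intersection(*(set(c.index) for c in per_cohort))
    if not common:
        raise ValueError("cohorts share no gene IDs")
    n_sig = pd.Series(0, index=pd.Index(sorted(all_genes), name="gene"))
    for res in per_cohort:
        sig = res.index[res["significant"]]
        n_sig.loc[sig] += 1
    selected = sorted(n_sig.index[n_sig >= min_sets])
    logger.info(
        "differential_selection: %d/%d genes selected in >=%d of %d cohorts",
        len(selected), len(n_sig), min_sets, len(cohorts),
    )
    if return_details:
        return selected, pd.DataFrame({"n_significant": n_sig})
    return selected


def keyword_filter(
    genes: list[str], annotations: dict, keywords: list[str]
) -> pd.DataFrame:
    """Retain genes whose free-text annotation matches any keyword.

    Matching is case-insensitive on whole words ("cell" does not match
    "cellular"). Returns a table with the match provenance; genes without an
    annotation entry are retained=False and logged.
    """
    patterns = [
        (kw, re.compile(r"(?<!\w)" + re.escape(kw) + r"(?!\w)", re.IGNORECASE))
        for kw in keywords
    ]
    rows = []
    for g in genes:
        text = annotations.get(g)
        if text is None:
            logger.warning("keyword_filter: no annotation for %s", g)
            rows.append({"gene": g, "retained": False, "matched_keywords": ""})
            continue
        hits = [kw for kw, pat in patterns if pat.search(text)]
        rows.append(
            {"gene": g, "retained": bool(hits), "matched_keywords": ";".join(hits)}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ssGSEA scoring


@dataclass
class SignatureScores:
    scores: pd.Series  # one score per sample
    gene_set_name: str
    alpha: float
    n_set_genes_used: int


def _ssgsea_sample(x: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """ssGSEA running-sum score for one sample (vector of expression values)."""
    n = x.size
    ranks = stats.rankdata(x)  # ascending, average ties
    order = np.argsort(-x, kind="stable")  # most expressed first
    in_ordered = in_set[order]
    w = np.where(in_ordered, ranks[order] ** alpha, 0.0)
    denom_in = w.sum()
    n_out = n - int(in_set.sum())
    p_in = np.cumsum(w) / denom_in
    p_out = np.cumsum(~in_ordered) / n_out
    return float((p_in - p_out).sum())


def ssgsea_score(
    cohort: ExpressionCohort, gene_set: GeneSet, alpha: float = 0.25
) -> SignatureScores:
    """Score every sample of a cohort against one gene set.

    Missing set genes are dropped (and counted); a constant sample (all
    values tied) scores 0 with a warning.
    """
    present = [g for g in gene_set.genes if g in cohort.values.index]
    n_missing = len(gene_set.genes) - len(present)
    if not present:
        raise ValueError(f"no genes of set {gene_set.name!r} present in cohort")
    if n_missing:
        logger.warning(
            "ssgsea_score: %d/%d set genes missing from cohort %s",
            n_missing, len(gene_set.genes), cohort.name,
        )
    if len(present) >= cohort.n_genes:
        raise ValueError("gene set covers the whole matrix; no out-of-set genes")
    in_set = cohort.values.index.isin(present)
    mat = cohort.values.to_numpy()
    scores = np.empty(cohort.n_samples)
    for j in range(cohort.n_samples):
        col = mat[:, j]
        if np.all(col == col[0]):
            logger.warning("ssgsea_score: constant sample %s scored 0", cohort.sample_ids[j])
            scores[j] = 0.0
        else:
            scores[j] = _ssgsea_sample(col, in_set, alpha)
    return SignatureScores(
        scores=pd.Series(scores, index=cohort.values.columns, name="score"),
        gene_set_name=gene_set.name,
        alpha=alpha,
        n_set_genes_used=len(present),
    )


# ---------------------------------------------------------------------------
# score clustering


@dataclass
class GroupAssignment:
    labels: pd.Series  # per-sample group label
    cluster_means: pd.Series  # label -> mean score, descending
    seed: int


def _group_names(k: int) -> list[str]:
    if k == 1:
        return ["high"]
    if k == 2:
        return ["high", "low"]
    if k == 3:
        return ["high", "intermediate", "low"]
    return [f"group{i + 1}" for i in range(k)]


def cluster_scores(scores: pd.Series, k: int = 3, seed: int = 0) -> GroupAssignment:
    """1-D k-means on signature scores, relabelled by descending cluster mean."""
    values = np.asarray(scores, dtype=float)
    if np.unique(values).size < k:
        raise ValueError(f"need >= {k} distinct score values for k={k}")
    km = KMeans(n_clusters=k, n_init=50, random_state=seed, tol=1e-10)
    raw = km.fit_predict(values.reshape(-1, 1))
    means = pd.Series(km.cluster_centers_.ravel())
    order = means.sort_values(ascending=False).index  # cluster id by descending mean
    names = _group_names(k)
    mapping = {cid: names[rank] for rank, cid in enumerate(order)}
    labels = pd.Series([mapping[c] for c in raw], index=scores.index, name="group")
    cluster_means = pd.Series(
        {names[rank]: float(means[cid]) for rank, cid in enumerate(order)}
    )
    return GroupAssignment(labels=labels, cluster_means=cluster_means, seed=seed)


# ---------------------------------------------------------------------------
# survival analyses


@dataclass
class SurvivalComparison:
    groups: tuple
    logrank_statistic: float
    p_value: float
    n_per_group: dict
    median_followup: float
    km_curves: pd.DataFrame | None = None


def km_logrank(
    time, event, labels, compare: tuple = ("high", "low"), km_curves: bool = True
) -> SurvivalComparison:
    """Two-group logrank test (chi-square, 1 df) with Kaplan-Meier step tables."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    labels = np.asarray(labels)
    a, b = compare
    mask_a, mask_b = labels == a, labels == b
    if mask_a.sum() == 0 or mask_b.sum() == 0:
        raise ValueError(f"empty comparison group among {compare}")
    pooled_events = event[mask_a | mask_b].sum()
    if pooled_events == 0:
        raise ValueError("no events observed")
    res = logrank_test(time[mask_a], time[mask_b], event[mask_a], event[mask_b])
    curves = None
    if km_curves:
        frames = []
        for g, m in ((a, mask_a), (b, mask_b)):
            kmf = KaplanMeierFitter()
            kmf.fit(time[m], event[m], label=str(g))
            sf = kmf.survival_function_.reset_index()
            sf.columns = ["time", "survival"]
            sf.insert(0, "group", str(g))
            frames.append(sf)
        curves = pd.concat(frames, ignore_index=True)
    return SurvivalComparison(
        groups=compare,
        logrank_statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        n_per_group={a: int(mask_a.sum()), b: int(mask_b.sum())},
        median_followup=float(np.median(time[mask_a | mask_b])),
        km_curves=curves,
    )


def tertile_labels(values: pd.Series) -> pd.Series:
    """Split samples into low/intermediate/high tertiles of a gene's expression.

    Rank-based split (stable order breaks ties deterministically), equivalent
    to cutting at the 1/3 and 2/3 empirical quantiles for distinct values.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    order = np.argsort(v, kind="stable")
    n_low = n // 3
    n_high = n // 3
    labels = np.empty(n, dtype=object)
    labels[order[:n_low]] = "low"
    labels[order[n_low : n - n_high]] = "intermediate"
    labels[order[n - n_high :]] = "high"
    q1, q2 = np.quantile(v, [1 / 3, 2 / 3])
    if np.sum(v == q1) > 1 or np.sum(v == q2) > 1:
        logger.warning("tertile_labels: ties span a tertile boundary; stable order used")
    return pd.Series(labels, index=values.index, name="tertile")


def tertile_survival(cohort: ExpressionCohort, gene: str) -> SurvivalComparison:
    """Logrank comparison of the top vs bottom expression tertile of one gene."""
    if gene not in cohort.values.index:
        raise ValueError(f"gene {gene!r} not in cohort")
    if cohort.n_samples < 6:
        raise ValueError("need >= 6 samples for tertile analysis")
    if cohort.annotations is None:
        raise ValueError("cohort lacks survival annotations")
    labels = tertile_labels(cohort.values.loc[gene])
    ann = cohort.annotations
    return km_logrank(ann["time"], ann["event"], labels, compare=("high", "low"))


# ---------------------------------------------------------------------------
# correlation / ANOVA characterisation


def correlation_table(cohort: ExpressionCohort, gene_set: GeneSet) -> pd.DataFrame:
    """Pearson correlation of each set gene with the per-sample set-mean expression."""
    if cohort.n_samples < 3:
        raise ValueError("need >= 3 samples")
    present = [g for g in gene_set.genes if g in cohort.values.index]
    if not present:
        raise ValueError("no set genes present in cohort")
    set_mean = cohort.set_mean(present)
    rows = []
    for g in present:
        x = cohort.values.loc[g]
        if np.std(x.to_numpy()) == 0:
            rows.append({"gene": g, "pcc": np.nan, "pvalue": np.nan})
            continue
        r, p = stats.pearsonr(x, set_mean)
        rows.append({"gene": g, "pcc": float(r), "pvalue": float(p)})
    return pd.DataFrame(rows)


def aggregate_correlations(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Across cohorts: mean PCC, standard error, and mean -log10(p) per gene."""
    cat = pd.concat(tables, ignore_index=True)
    cat["neglog10p"] = -np.log10(cat["pvalue"])

    def _agg(g):
        r = g["pcc"].dropna()
        return pd.Series(
            {
                "mean_pcc": r.mean(),
                "stderr_pcc": r.std(ddof=1) / np.sqrt(len(r)) if len(r) > 1 else np.nan,
                "mean_neglog10p": g["neglog10p"].dropna().mean(),
                "n_cohorts": len(r),
            }
        )

    return cat.groupby("gene", sort=True).apply(_agg, include_groups=False).reset_index()


def anova_by_sample_type(cohort: ExpressionCohort, gene_set: GeneSet):
    """One-way ANOVA of per-sample mean signature expression across sample types.

    Types with a single sample are excluded with a warning. Returns
    (F statistic, p-value, groups used).
    """
    if cohort.annotations is None or "sample_type" not in cohort.annotations.columns:
        raise ValueError("cohort lacks sample_type annotations")
    set_mean = cohort.set_mean(gene_set.genes)
    types = cohort.annotations["sample_type"]
    groups, used = [], []
    for t, idx in types.groupby(types).groups.items():
        vals = set_mean.loc[idx]
        if len(vals) < 2:
            logger.warning("anova_by_sample_type: type %r has <2 samples, excluded", t)
            continue
        groups.append(vals.to_numpy())
        used.append(t)
    if len(groups) < 2:
        raise ValueError("need >= 2 sample types with >= 2 samples each")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p), used
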