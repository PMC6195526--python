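"""Synthetic-data generators emulating the study's four input types.

Each generator is a pure function of (params, seed) and returns both the data
container the analysis modules consume and a *truth record* sufficient to
score downstream recovery: planted subtype labels and hazard ratio for the
cohort, planted knockdown fractions and Bliss-excess synergy for the screen,
planted growth-rate inhibition for the confluence curves, and the planted
post-metaphase probabilities for the mitotic counts.

The screen generator reproduces the study layout: a 48-gene library with four
individual siRNAs per gene, three replicate experiments, two arms (vehicle and
docetaxel at the per-line EC30), and 96-well plates each carrying eight
non-targeting and eight positive-control wells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .types import (
    COND_DRUG,
    COND_VEHICLE,
    ConfluenceTable,
    ExpressionCohort,
    MitoticCountTable,
    PlateSet,
    ROLE_NTC,
    ROLE_POS,
    ROLE_SAMPLE,
)

logger = logging.getLogger("sigscreen")

_ROWS = "ABCDEFGH"


# ---------------------------------------------------------------------------
# expression cohort


@dataclass
class CohortSimParams:
    """Parameters of the synthetic expression + survival cohort.

    Signature genes receive, in aggressive samples only, a log2 shift of
    ``effect_delta`` plus a shared per-sample latent factor with loading
    ``latent_load``; the shared factor induces the signature co-expression
    the correlation analysis expects. Survival times
    are exponential with the hazard multiplied by ``hazard_ratio`` in
    aggressive samples; censoring is independent exponential with its rate
    solved numerically to achieve ``censor_rate``.

    Sample types (primary / metastasis / CRPC) are drawn with probabilities
    conditioned on the planted subtype — aggressive tumours are enriched for
    metastatic and castration-resistant disease, which is what makes the
    set-mean expression differ by sample type. An optional direct per-type
    expression shift (``sample_type_shifts``) is available but defaults to 0.
    ``signature_indices`` pins the planted signature to fixed gene positions
    so several simulated cohorts can share one signature.
    """

    n_samples: int = 200
    n_genes: int = 2000
    signature_size: int = 48
    frac_aggressive: float = 0.3
    effect_delta: float = 1.0
    latent_load: float = 0.6
    noise_sd: float = 1.0
    baseline_hazard: float = 0.02
    hazard_ratio: float = 3.0
    censor_rate: float = 0.3
    signature_indices: list | None = None
    sample_type_shifts: dict = field(
        default_factory=lambda: {"primary": 0.0, "metastasis": 0.0, "CRPC": 0.0}
    )
    sample_type_probs: dict = field(
        default_factory=lambda: {
            "aggressive": {"primary": 0.35, "metastasis": 0.40, "CRPC": 0.25},
            "normal-like": {"primary": 0.85, "metastasis": 0.12, "CRPC": 0.03},
        }
    )

    def __post_init__(self) -> None:
        if self.signature_size > self.n_genes:
            raise ValueError("signature_size must be <= n_genes")
        if self.hazard_ratio <= 0 or self.baseline_hazard <= 0:
            raise ValueError("hazards must be strictly positive")
        if not (0 < self.frac_aggressive < 1):
            raise ValueError("frac_aggressive must lie in (0, 1)")
        if not (0 <= self.latent_load < 1):
            raise ValueError("latent_load must lie in [0, 1)")
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class CohortTruth:
    signature_genes: list
    aggressive: pd.Series  # bool per sample
    hazard_ratio: float
    censor_rate_target: float
    censor_rate_achieved: float


def _solve_censor_rate(lams: np.ndarray, target: float) -> float:
    """Exponential censoring rate c with mean_s P(C < T_s) = target."""

    def frac_censored(c):
        return float(np.mean(c / (c + lams))) - target

    lo, hi = 1e-12, 1e12
    return brentq(frac_censored, lo, hi, maxiter=200)


def simulate_cohort(params: CohortSimParams, seed: int) -> tuple[ExpressionCohort, CohortTruth]:
    rng = np.random.default_rng(seed)
    p = params
    if p.noise_sd == 0 and p.latent_load == 0 and p.effect_delta == 0:
        logger.warning("simulate_cohort: degenerate params, signature unidentifiable")

    genes = [f"G{i + 1:05d}" for i in range(p.n_genes)]
    samples = [f"S{i + 1:04d}" for i in range(p.n_samples)]
    if p.signature_indices is not None:
        sig_idx = np.sort(np.asarray(p.signature_indices, dtype=int))
        if sig_idx.size != p.signature_size:
            raise ValueError("signature_indices length must equal signature_size")
    else:
        sig_idx = np.sort(rng.choice(p.n_genes, size=p.signature_size, replace=False))
    sig_genes = [genes[i] for i in sig_idx]

    n_aggr = int(round(p.frac_aggressive * p.n_samples))
    aggressive = np.zeros(p.n_samples, dtype=bool)
    aggressive[rng.permutation(p.n_samples)[:n_aggr]] = True

    type_labels = list(p.sample_type_shifts)
    sample_type = np.empty(p.n_samples, dtype=object)
    for subtype, mask in (("aggressive", aggressive), ("normal-like", ~aggressive)):
        probs = np.array(
            [p.sample_type_probs[subtype].get(t, 0.0) for t in type_labels], dtype=float
        )
        probs = probs / probs.sum()
        sample_type[mask] = rng.choice(type_labels, size=int(mask.sum()), p=probs)
    type_shift = np.array([p.sample_type_shifts[t] for t in sample_type])

    baseline = rng.normal(7.0, 1.0, size=p.n_genes)
    latent = rng.normal(0.0, 1.0, size=p.n_samples)
    x = baseline[:, None] + p.noise_sd * rng.normal(size=(p.n_genes, p.n_samples))
    sig_signal = (p.effect_delta + p.latent_load * latent) * aggressive + type_shift
    x[sig_idx, :] += sig_signal[None, :]

    lam = p.baseline_hazard * np.where(aggressive, p.hazard_ratio, 1.0)
    event_time = rng.exponential(1.0 / lam)
    if p.censor_rate > 0:
        c = _solve_censor_rate(lam, p.censor_rate)
        censor_time = rng.exponential(1.0 / c, size=p.n_samples)
    else:
        censor_time = np.full(p.n_samples, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    ann = pd.DataFrame(
        {
            "time": time,
            "event": event,
            "sample_type": sample_type,
            "subtype": np.where(aggressive, "aggressive", "normal-like"),
        },
        index=pd.Index(samples, name="sample_id"),
    )
    cohort = ExpressionCohort(
        values=pd.DataFrame(x, index=genes, columns=samples),
        annotations=ann,
        name=f"sim_seed{seed}",
    )
    truth = CohortTruth(
        signature_genes=sig_genes,
        aggressive=pd.Series(aggressive, index=samples),
        hazard_ratio=p.hazard_ratio,
        censor_rate_target=p.censor_rate,
        censor_rate_achieved=float(1 - event.mean()),
    )
    logger.info(
        "simulate_cohort: seed=%d n=%d genes=%d censored=%.2f",
        seed, p.n_samples, p.n_genes, truth.censor_rate_achieved,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# viability screen


@dataclass
class ScreenSimParams:
    """Parameters of the synthetic deconvoluted viability screen.

    ``gene_effects`` maps gene -> true knockdown growth inhibition fraction
    (either one float for all lines or a per-line map); unset genes draw a
    uniform effect in [0.05, 0.5] per gene, shared across lines. Each siRNA
    has an efficacy multiplier (default drawn uniform in [0.4, 1]).
    ``drug_effect`` is the fractional inhibition of the drug alone (the EC30
    design point, 0.30). ``bliss_excess`` maps (gene, cell line) -> beta, the
    planted excess of combined inhibition over the Bliss independence
    prediction; beta > 0 plants synergy with an analytic combination index
    (f_A + f_B - f_A f_B) / (f_A + f_B - f_A f_B + beta).
    """

    genes: int = 48
    sirnas_per_gene: int = 4
    replicates: int = 3
    cell_lines: tuple = ("LNCaP", "PC3", "DU145")
    ntc_wells: int = 8
    pos_wells: int = 8
    mu_ntc: float = 2000.0
    cv: float = 0.05
    gene_effects: dict | None = None
    sirna_efficacy: dict | None = None
    drug_effect: float | dict = 0.30
    bliss_excess: dict = field(default_factory=dict)
    offtarget_sd: float = 0.02
    pos_effect: float = 0.85
    gene_names: list | None = None

    def __post_init__(self) -> None:
        if self.cv <= 0 or self.mu_ntc <= 0:
            raise ValueError("mu_ntc and cv must be strictly positive")
        if self.offtarget_sd < 0:
            raise ValueError("offtarget_sd must be non-negative")
        if not (0 <= self.pos_effect <= 1):
            raise ValueError("pos_effect must lie in [0, 1]")


@dataclass
class ScreenTruth:
    knockdown: pd.DataFrame  # (cell_line, gene, sirna_id) -> f, beta, expected_ci
    drug_effect: dict
    clipped_fraction: float


def _default_gene_names(n: int) -> list[str]:
    if n == 48:
        from .io import load_signature_geneset

        return list(load_signature_geneset().genes)
    return [f"GENE{i + 1:03d}" for i in range(n)]


def _layout_plate(samples_chunk, ntc_wells, pos_wells):
    """Assign 96-well addresses: samples in columns 1-10, NTC col 11, POS col 12."""
    wells = []
    for j, rec in enumerate(samples_chunk):
        row, col = _ROWS[j % 8], j // 8 + 1
        wells.append((f"{row}{col:02d}", *rec))
    ctrl = []
    for j in range(ntc_wells):
        ctrl.append((f"{_ROWS[j % 8]}{11 + j // 8:02d}", ROLE_NTC))
    for j in range(pos_wells):
        ctrl.append((f"{_ROWS[j % 8]}{12 + j // 8:02d}", ROLE_POS))
    return wells, ctrl


def simulate_screen(params: ScreenSimParams, seed: int) -> tuple[PlateSet, ScreenTruth]:
    rng = np.random.default_rng(seed)
    p = params
    genes = list(p.gene_names) if p.gene_names else _default_gene_names(p.genes)
    if len(genes) != p.genes:
        raise ValueError("gene_names length must equal genes")
    sirnas = {g: [f"{g}_si{k + 1}" for k in range(p.sirnas_per_gene)] for g in genes}

    drug_effect = (
        {L: float(p.drug_effect) for L in p.cell_lines}
        if np.isscalar(p.drug_effect)
        else dict(p.drug_effect)
    )

    def gene_effect(g, line, drawn):
        if p.gene_effects is None or g not in p.gene_effects:
            return drawn[g]
        v = p.gene_effects[g]
        return float(v[line]) if isinstance(v, dict) else float(v)

    drawn = {g: rng.uniform(0.05, 0.5) for g in genes}
    eff = {}
    for g in genes:
        for s in sirnas[g]:
            if p.sirna_efficacy is not None and s in p.sirna_efficacy:
                eff[s] = float(p.sirna_efficacy[s])
            else:
                eff[s] = rng.uniform(0.4, 1.0) if p.sirna_efficacy is None else 1.0

    # true knockdown fraction per (line, gene, sirna), off-target noise included
    truth_rows = []
    f_true = {}
    for line in p.cell_lines:
        fb = drug_effect[line]
        for g in genes:
            beta = float(p.bliss_excess.get((g, line), 0.0))
            for s in sirnas[g]:
                f = gene_effect(g, line, drawn) * eff[s]
                if p.offtarget_sd > 0:
                    f += rng.normal(0.0, p.offtarget_sd)
                f = float(np.clip(f, 0.0, 1.0))
                f_true[(line, g, s)] = f
                bliss = f + fb - f * fb
                fab = min(bliss + beta, 1.0)
                truth_rows.append(
                    {
                        "cell_line": line,
                        "gene": g,
                        "sirna_id": s,
                        "f_knockdown": f,
                        "drug_effect": fb,
                        "beta": beta,
                        "expected_ci": bliss / fab if fab > 0 else np.inf,
                    }
                )

    sample_per_plate = 96 - p.ntc_wells - p.pos_wells
    rows = []
    n_clip = 0
    n_wells = 0
    flat = [(g, s) for g in genes for s in sirnas[g]]
    for line in p.cell_lines:
        fb = drug_effect[line]
        for rep in range(1, p.replicates + 1):
            for cond in (COND_VEHICLE, COND_DRUG):
                chunks = [
                    flat[i : i + sample_per_plate]
                    for i in range(0, len(flat), sample_per_plate)
                ]
                for pi, chunk in enumerate(chunks, start=1):
                    plate_id = f"{line}_{cond}_r{rep}_p{pi}"
                    swells, cwells = _layout_plate(chunk, p.ntc_wells, p.pos_wells)
                    for well, g, s in swells:
                        f = f_true[(line, g, s)]
                        if cond == COND_VEHICLE:
                            surv = 1.0 - f
                        else:
                            beta = float(p.bliss_excess.get((g, line), 0.0))
                            surv = (1.0 - f) * (1.0 - fb) - beta
                        clipped = np.clip(surv, 0.0, 1.0)
                        n_clip += int(clipped != surv)
                        n_wells += 1
                        rows.append((plate_id, well, line, cond, ROLE_SAMPLE, g, s, rep, clipped))
                    for well, role in cwells:
                        f = 0.0 if role == ROLE_NTC else p.pos_effect
                        surv = (1.0 - f) * (1.0 - fb) if cond == COND_DRUG else 1.0 - f
                        n_wells += 1
                        rows.append((plate_id, well, line, cond, role, "", "", rep, surv))

    df = pd.DataFrame(
        rows,
        columns=[
            "plate_id", "well", "cell_line", "condition", "role",
            "gene", "sirna_id", "replicate", "survival",
        ],
    )
    counts = rng.normal(p.mu_ntc * df["survival"].to_numpy(), p.cv * p.mu_ntc)
    df["nuclei_count"] = np.round(np.maximum(counts, 0.0)).astype(int)
    df = df.drop(columns=["survival"])

    clipped_fraction = n_clip / max(n_wells, 1)
    if clipped_fraction > 0.10:
        logger.warning(
            "simulate_screen: %.1f%% of sample wells clipped to [0,1]", 100 * clipped_fraction
        )
    truth = ScreenTruth(
        knockdown=pd.DataFrame(truth_rows),
        drug_effect=drug_effect,
        clipped_fraction=clipped_fraction,
    )
    logger.info(
        "simulate_screen: seed=%d lines=%d genes=%d wells=%d clipped=%.3f",
        seed, len(p.cell_lines), p.genes, len(df), clipped_fraction,
    )
    return PlateSet(wells=df), truth


def wells_per_line(params: ScreenSimParams) -> int:
    """Deterministic well count per cell line implied by the layout policy."""
    n_samples = params.genes * params.sirnas_per_gene
    sample_per_plate = 96 - params.ntc_wells - params.pos_wells
    n_plates = -(-n_samples // sample_per_plate)
    per_arm = n_samples + n_plates * (params.ntc_wells + params.pos_wells)
    return 2 * params.replicates * per_arm


# ---------------------------------------------------------------------------
# confluence growth curves


@dataclass
class GrowthSimParams:
    """Logistic growth with the rate scaled by (1 - inhibition) after drug addition."""

    carrying_capacity: float = 100.0
    c0: float = 10.0
    growth_rate: float = 0.03  # per hour
    drug_addition_time: float = 24.0
    rate_inhibition: dict = field(default_factory=lambda: {"DMSO": 0.0, "DCT": 0.6})
    scan_interval: float = 2.0
    horizon: float = 120.0
    meas_sd: float = 1.0
    wells_per_condition: int = 3
    n_experiments: int = 3
    seeding_cv: float = 0.1
    cell_line: str = "LNCaP"

    def __post_init__(self) -> None:
        if self.c0 >= self.carrying_capacity:
            raise ValueError("c0 must be below carrying_capacity")
        if self.horizon <= self.drug_addition_time:
            raise ValueError("horizon must exceed drug_addition_time")
        if self.meas_sd < 0 or self.seeding_cv < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass
class GrowthTruth:
    rate_inhibition: dict
    growth_rate: float


def _logistic(t, c0, k, r):
    return k / (1.0 + ((k - c0) / c0) * np.exp(-r * t))


def simulate_confluence(params: GrowthSimParams, seed: int) -> tuple[ConfluenceTable, GrowthTruth]:
    rng = np.random.default_rng(seed)
    p = params
    times = np.arange(0.0, p.horizon + 1e-9, p.scan_interval)
    ta = p.drug_addition_time
    rows = []
    for exp in range(1, p.n_experiments + 1):
        # per-experiment seeding density variation; normalisation must cancel it
        seed_factor = float(np.exp(rng.normal(0.0, p.seeding_cv)))
        for cond, inh in p.rate_inhibition.items():
            r_post = p.growth_rate * (1.0 - inh)
            for w in range(1, p.wells_per_condition + 1):
                c0 = p.c0 * seed_factor
                pre = _logistic(times[times <= ta], c0, p.carrying_capacity, p.growth_rate)
                c_ta = _logistic(np.array([ta]), c0, p.carrying_capacity, p.growth_rate)[0]
                post_t = times[times > ta] - ta
                post = _logistic(post_t, c_ta, p.carrying_capacity, r_post)
                curve = np.concatenate([pre, post])
                # two images per well, averaged
                meas = curve + rng.normal(0.0, p.meas_sd, size=(2, curve.size)).mean(axis=0)
                for t, c in zip(times, meas):
                    rows.append((exp, f"{cond}_w{w}", p.cell_line, cond, t, c))
    df = pd.DataFrame(
        rows, columns=["experiment", "well", "cell_line", "condition", "time_h", "confluence"]
    )
    truth = GrowthTruth(rate_inhibition=dict(p.rate_inhibition), growth_rate=p.growth_rate)
    logger.info(
        "simulate_confluence: seed=%d experiments=%d scans=%d", seed, p.n_experiments, times.size
    )
    return ConfluenceTable(measurements=df, drug_addition_time=ta), truth


# ---------------------------------------------------------------------------
# mitotic phase counts


@dataclass
class MitoticSimParams:
    """Per-well mitotic cell counts: N ~ Poisson(lambda), post-metaphase ~ Binomial(N, p)."""

    lambda_mitotic: float = 150.0
    p_postmeta: dict = field(
        default_factory=lambda: {
            ("NTC", "DMSO"): 0.50,
            ("NTC", "DCT"): 0.375,
            ("siDLGAP5", "DMSO"): 0.45,
            ("siDLGAP5", "DCT"): 0.25,
            ("siAR", "DMSO"): 0.60,
            ("siAR", "DCT"): 0.58,
        }
    )
    wells: int = 3
    experiments: int = 3

    def __post_init__(self) -> None:
        if self.lambda_mitotic < 0:
            raise ValueError("lambda_mitotic must be non-negative")
        for k, v in self.p_postmeta.items():
            if not (0 < v < 1):
                raise ValueError(f"p_postmeta[{k}] must lie in (0, 1)")


@dataclass
class MitoticTruth:
    p_postmeta: dict
    flagged_wells: int  # wells with zero mitotic cells (ratio undefined downstream)


def simulate_mitotic(params: MitoticSimParams, seed: int) -> tuple[MitoticCountTable, MitoticTruth]:
    rng = np.random.default_rng(seed)
    p = params
    rows = []
    flagged = 0
    for exp in range(1, p.experiments + 1):
        for (sirna, drug), prob in p.p_postmeta.items():
            for w in range(1, p.wells + 1):
                n = rng.poisson(p.lambda_mitotic)
                post = rng.binomial(n, prob) if n > 0 else 0
                if n == 0:
                    flagged += 1
                rows.append((exp, f"{sirna}_{drug}_w{w}", sirna, drug, n - post, post))
    df = pd.DataFrame(
        rows,
        columns=["experiment", "well", "sirna", "drug", "metaphase_count", "postmeta_count"],
    )
    if flagged:
        logger.warning("simulate_mitotic: %d wells with zero mitotic cells", flagged)
    truth = MitoticTruth(p_postmeta=dict(p.p_postmeta), flagged_wells=flagged)
    return MitoticCountTable(counts=df), truth
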