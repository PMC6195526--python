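import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from sigscreen import simulate as sim
from sigscreen import signature as sg
from sigscreen.types import ExpressionCohort, GeneSet


# ---------------------------------------------------------------------------
# independent oracles


def ssgsea_bruteforce(expr: np.ndarray, set_mask: np.ndarray, alpha: float) -> float:
    """Direct double-loop over ranked positions of the weighted ECDF difference."""
    n = len(expr)
    ranks = stats.rankdata(expr)
    order = sorted(range(n), key=lambda i: (-expr[i], i))
    sum_w = sum(ranks[i] ** alpha for i in order if set_mask[i])
    n_out = n - int(np.sum(set_mask))
    score = 0.0
    for stop in range(1, n + 1):
        p_in = 0.0
        p_out = 0.0
        for i in order[:stop]:
            if set_mask[i]:
                p_in += ranks[i] ** alpha / sum_w
            else:
                p_out += 1.0 / n_out
        score += p_in - p_out
    return score


def logrank_bruteforce(time, event, group):
    """Risk-set table logrank statistic with hypergeometric tie variance."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group, bool)  # True = group A
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n = at_risk.sum()
        n_a = (at_risk & group).sum()
        d = ((time == t) & (event == 1)).sum()
        d_a = ((time == t) & (event == 1) & group).sum()
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return chi2, float(stats.chi2.sf(chi2, 1))


def _cohort_from_matrix(mat, ann=None):
    values = pd.DataFrame(
        mat, index=[f"g{i}" for i in range(mat.shape[0])],
        columns=[f"s{j}" for j in range(mat.shape[1])],
    )
    return ExpressionCohort(values=values, annotations=ann)


# ---------------------------------------------------------------------------
# ssGSEA


class TestSsgsea:
    def test_hand_example_alpha_zero(self):
        """4 genes (10,8,2,1), set={g0,g1}, alpha=0: running sum 0.5+1+0.5+0."""
        cohort = _cohort_from_matrix(np.array([[10.0], [8.0], [2.0], [1.0]]))
        gs = GeneSet("S", "d", ["g0", "g1"])
        res = sg.ssgsea_score(cohort, gs, alpha=0.0)
        expected = ssgsea_bruteforce(
            np.array([10.0, 8.0, 2.0, 1.0]), np.array([True, True, False, False]), 0.0
        )
        assert expected == pytest.approx(2.0)
        assert res.scores.iloc[0] == pytest.approx(expected)

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n_genes = rng.integers(5, 21)
            n_samples = rng.integers(1, 6)
            mat = rng.normal(size=(n_genes, n_samples))
            if rng.random() < 0.3:  # exercise tie handling
                mat = np.round(mat, 1)
            k = rng.integers(1, n_genes - 1)
            members = rng.choice(n_genes, size=k, replace=False)
            mask = np.zeros(n_genes, bool)
            mask[members] = True
            alpha = float(rng.choice([0.0, 0.25, 1.0]))
            cohort = _cohort_from_matrix(mat)
            gs = GeneSet("S", "d", [f"g{i}" for i in members])
            res = sg.ssgsea_score(cohort, gs, alpha=alpha)
            for j in range(n_samples):
                expected = ssgsea_bruteforce(mat[:, j], mask, alpha)
                assert res.scores.iloc[j] == pytest.approx(expected, abs=1e-9)

    def test_top_k_set_scores_above_bottom_k(self):
        rng = np.random.default_rng(1)
        mat = rng.normal(size=(30, 4))
        ranks = np.argsort(-mat.mean(axis=1))
        cohort = _cohort_from_matrix(mat)
        top = GeneSet("top", "d", [f"g{i}" for i in ranks[:5]])
        bottom = GeneSet("bot", "d", [f"g{i}" for i in ranks[-5:]])
        s_top = sg.ssgsea_score(cohort, top).scores
        s_bot = sg.ssgsea_score(cohort, bottom).scores
        assert (s_top > s_bot).all()

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_transform_invariance(self, seed):
        """Rank-based score is unchanged by strictly monotone transforms."""
        rng = np.random.default_rng(seed)
        mat = rng.normal(size=(15, 3))
        gs = GeneSet("S", "d", [f"g{i}" for i in rng.choice(15, 4, replace=False)])
        a = sg.ssgsea_score(_cohort_from_matrix(mat), gs).scores
        b = sg.ssgsea_score(_cohort_from_matrix(np.exp(mat) + 3), gs).scores
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_sample_permutation_permutes_scores(self):
        rng = np.random.default_rng(3)
        mat = rng.normal(size=(12, 5))
        gs = GeneSet("S", "d", ["g0", "g3", "g7"])
        a = sg.ssgsea_score(_cohort_from_matrix(mat), gs).scores
        perm = [4, 2, 0, 1, 3]
        b = sg.ssgsea_score(_cohort_from_matrix(mat[:, perm]), gs).scores
        np.testing.assert_allclose(b.to_numpy(), a.to_numpy()[perm], atol=1e-12)

    def test_missing_set_genes_counted(self):
        cohort = _cohort_from_matrix(np.random.default_rng(0).normal(size=(10, 2)))
        gs = GeneSet("S", "d", ["g1", "g2", "NOT_THERE"])
        res = sg.ssgsea_score(cohort, gs)
        assert res.n_set_genes_used == 2

    def test_no_set_genes_is_error(self):
        cohort = _cohort_from_matrix(np.zeros((3, 2)) + np.arange(3)[:, None])
        with pytest.raises(ValueError, match="no genes"):
            sg.ssgsea_score(cohort, GeneSet("S", "d", ["absent"]))

    def test_constant_sample_scores_zero(self):
        mat = np.column_stack([np.ones(5), np.arange(5, dtype=float)])
        res = sg.ssgsea_score(_cohort_from_matrix(mat), GeneSet("S", "d", ["g0", "g4"]))
        assert res.scores.iloc[0] == 0.0


# ---------------------------------------------------------------------------
# differential selection and keyword curation


class TestDifferentialSelection:
    def _cohorts(self, n_cohorts=3, seed0=1):
        p = sim.CohortSimParams(
            n_samples=200, n_genes=400, signature_size=10, effect_delta=2.0,
            signature_indices=list(range(10)),
        )
        return [sim.simulate_cohort(p, seed=seed0 + i)[0] for i in range(n_cohorts)]

    def test_planted_genes_recovered(self):
        selected = sg.differential_selection(self._cohorts())
        assert set(selected) == {f"G{i + 1:05d}" for i in range(10)}

    def test_single_cohort_significance_not_enough(self):
        cohorts = self._cohorts(2)
        null = sim.simulate_cohort(
            sim.CohortSimParams(n_samples=200, n_genes=400, signature_size=10,
                                effect_delta=0.0, latent_load=0.0,
                                signature_indices=list(range(10))),
            seed=99,
        )[0]
        # planted only in 1 of 3 cohorts -> excluded at min_sets=3
        sel = sg.differential_selection([cohorts[0], null, null], min_sets=3)
        assert sel == []

    def test_min_sets_one_is_union(self):
        cohorts = self._cohorts(2)
        sel1 = set(sg.differential_selection(cohorts, min_sets=1))
        per = [set(sg.differential_selection([c, c], min_sets=2)) for c in cohorts]
        assert per[0] | per[1] <= sel1

    def test_null_gene_rarely_selected(self):
        """Type-I control: under the complete null almost nothing is selected."""
        p = sim.CohortSimParams(
            n_samples=100, n_genes=1000, signature_size=10, effect_delta=0.0,
            latent_load=0.0, signature_indices=list(range(10)),
        )
        cohorts = [sim.simulate_cohort(p, seed=10 + i)[0] for i in range(3)]
        sel = sg.differential_selection(cohorts)
        assert len(sel) < 0.05 * 1000

    def test_small_group_rejected(self):
        p = sim.CohortSimParams(n_samples=6, n_genes=20, signature_size=2,
                                frac_aggressive=0.2)
        cohorts = [sim.simulate_cohort(p, seed=i)[0] for i in range(2)]
        with pytest.raises(ValueError, match=">= 3 samples"):
            sg.differential_selection(cohorts)


class TestKeywordFilter:
    def test_whole_word_match(self):
        res = sg.keyword_filter(
            ["A", "B", "C"],
            {"A": "regulates cell cycle", "B": "cellular membrane", "C": "p53 target"},
            ["cell cycle", "p53"],
        ).set_index("gene")
        assert res.loc["A", "retained"] and res.loc["C", "retained"]
        assert not res.loc["B", "retained"]

    def test_word_boundary(self):
        res = sg.keyword_filter(["B"], {"B": "cellular"}, ["cell"])
        assert not res["retained"].iloc[0]

    def test_empty_keywords_retain_nothing(self):
        res = sg.keyword_filter(["A"], {"A": "anything"}, [])
        assert not res["retained"].any()

    def test_missing_annotation_not_retained(self):
        res = sg.keyword_filter(["A"], {}, ["cell"])
        assert not res["retained"].iloc[0]


# ---------------------------------------------------------------------------
# clustering


class TestClusterScores:
    def test_three_gaussian_recovery(self):
        rng = np.random.default_rng(0)
        ari_scores = []
        from sklearn.metrics import adjusted_rand_score

        for s in range(10):
            truth = rng.integers(0, 3, 300)
            scores = pd.Series(rng.normal(truth * 3.0 - 3.0, 0.3))
            grp = sg.cluster_scores(scores, k=3, seed=s)
            ari_scores.append(adjusted_rand_score(truth, grp.labels))
        assert min(ari_scores) > 0.95

    def test_labels_ordered_by_mean(self):
        scores = pd.Series([0.0, 0.1, 5.0, 5.1, 10.0, 10.1])
        grp = sg.cluster_scores(scores, k=3, seed=0)
        assert grp.labels.iloc[0] == "low" and grp.labels.iloc[-1] == "high"
        means = grp.cluster_means
        assert means["high"] > means["intermediate"] > means["low"]

    def test_k1_single_group(self):
        grp = sg.cluster_scores(pd.Series([1.0, 2.0, 3.0]), k=1, seed=0)
        assert set(grp.labels) == {"high"}

    def test_order_invariance(self):
        scores = pd.Series(np.random.default_rng(5).normal(size=60))
        a = sg.cluster_scores(scores, k=3, seed=1).labels
        perm = np.random.default_rng(6).permutation(60)
        b = sg.cluster_scores(scores.iloc[perm], k=3, seed=1).labels
        assert (b.sort_index() == a.sort_index()).all()

    def test_too_few_distinct_values(self):
        with pytest.raises(ValueError, match="distinct"):
            sg.cluster_scores(pd.Series([1.0, 1.0, 2.0]), k=3, seed=0)


# ---------------------------------------------------------------------------
# survival


class TestKmLogrank:
    def test_identical_groups_statistic_zero(self):
        time = [1, 2, 3, 4] * 2
        event = [1, 1, 1, 0] * 2
        labels = ["high"] * 4 + ["low"] * 4
        res = sg.km_logrank(time, event, labels)
        assert res.logrank_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_example_matches_bruteforce(self):
        time = [1, 2, 3, 4]
        event = [1, 1, 1, 1]
        labels = ["high", "high", "low", "low"]
        res = sg.km_logrank(time, event, labels)
        chi2, p = logrank_bruteforce(time, event, np.array(labels) == "high")
        assert res.logrank_statistic == pytest.approx(chi2, abs=1e-9)
        assert res.p_value == pytest.approx(p, abs=1e-9)

    def test_matches_bruteforce_on_small_configurations(self):
        """Exhaustive tiny configurations incl. ties and censoring."""
        import itertools

        n_checked = 0
        for n in (3, 4):
            for times in itertools.product((1, 2), repeat=n):
                for events in itertools.product((0, 1), repeat=n):
                    groups = np.array([True] * (n // 2) + [False] * (n - n // 2))
                    t = np.array(times, float)
                    e = np.array(events, int)
                    if e[groups].sum() + e[~groups].sum() == 0:
                        continue
                    res = sg.km_logrank(
                        t, e, np.where(groups, "high", "low"), km_curves=False
                    )
                    chi2, p = logrank_bruteforce(t, e, groups)
                    assert res.logrank_statistic == pytest.approx(chi2, abs=1e-9)
                    assert res.p_value == pytest.approx(p, abs=1e-9)
                    n_checked += 1
        assert n_checked > 100

    def test_no_events_is_error(self):
        with pytest.raises(ValueError, match="no events"):
            sg.km_logrank([1, 2], [0, 0], ["high", "low"])

    def test_km_curves_start_at_one(self):
        res = sg.km_logrank([1, 2, 3, 4], [1, 0, 1, 1], ["high", "high", "low", "low"])
        for _, grp in res.km_curves.groupby("group"):
            assert grp["survival"].iloc[0] == pytest.approx(1.0)


class TestTertiles:
    def test_n9_gives_3_3_3(self):
        labels = sg.tertile_labels(pd.Series(np.arange(9.0)))
        assert labels.value_counts().to_dict() == {"low": 3, "intermediate": 3, "high": 3}

    def test_prognostic_gene_detected(self):
        hits = 0
        for s in range(20):
            cohort, truth = sim.simulate_cohort(
                sim.CohortSimParams(n_samples=200, n_genes=50, signature_size=5,
                                    effect_delta=2.0, hazard_ratio=3.0),
                seed=s,
            )
            res = sg.tertile_survival(cohort, truth.signature_genes[0])
            hits += res.p_value < 0.05
        assert hits >= 15

    def test_tie_break_deterministic(self):
        v = pd.Series([1.0, 1.0, 1.0, 1.0, 2.0, 3.0])
        a = sg.tertile_labels(v)
        b = sg.tertile_labels(v)
        assert (a == b).all()


class TestCorrelationAnova:
    def test_gene_equal_to_set_mean_r1(self):
        rng = np.random.default_rng(0)
        g0, g1 = rng.normal(size=(2, 30))
        g2 = (g0 + g1) / 2  # equals the mean of {g0, g1, g2}
        cohort = _cohort_from_matrix(np.vstack([g0, g1, g2]))
        res = sg.correlation_table(cohort, GeneSet("S", "d", ["g0", "g1", "g2"]))
        r = res.set_index("gene").loc["g2", "pcc"]
        assert r == pytest.approx(1.0)

    def test_anticorrelated_gene(self):
        rng = np.random.default_rng(1)
        g0 = rng.normal(size=50)
        g1 = -3 * g0  # set mean = -g0, g0 anti-correlated with it
        cohort = _cohort_from_matrix(np.vstack([g0, g1]))
        res = sg.correlation_table(cohort, GeneSet("S", "d", ["g0", "g1"]))
        assert res.set_index("gene").loc["g0", "pcc"] == pytest.approx(-1.0)

    def test_independent_gene_low_correlation(self):
        """A noise gene inside a large set correlates weakly with the set mean.

        The set is large so that the gene's own 1/m contribution to the set
        mean stays well below the 0.3 bound.
        """
        ok = 0
        for s in range(40):
            rng = np.random.default_rng(s)
            mat = rng.normal(size=(200, 100))
            gs = GeneSet("S", "d", [f"g{i}" for i in range(200)])
            res = sg.correlation_table(_cohort_from_matrix(mat), gs)
            ok += abs(res.set_index("gene").loc["g42", "pcc"]) < 0.3
        assert ok >= 38

    def test_anova_null_f_near_one(self):
        fs = []
        rng = np.random.default_rng(0)
        for _ in range(300):
            x = rng.normal(size=60)
            f, _ = stats.f_oneway(x[:20], x[20:40], x[40:])
            fs.append(f)
        assert np.mean(fs) == pytest.approx(1.0, abs=0.15)

    def test_anova_detects_planted_type_shift(self):
        cohort, truth = sim.simulate_cohort(
            sim.CohortSimParams(
                n_samples=150, n_genes=100, signature_size=10, effect_delta=0.0,
                latent_load=0.0,
                sample_type_shifts={"primary": 0.0, "metastasis": 2.0, "CRPC": 2.0},
                sample_type_probs={
                    "aggressive": {"primary": 0.34, "metastasis": 0.33, "CRPC": 0.33},
                    "normal-like": {"primary": 0.34, "metastasis": 0.33, "CRPC": 0.33},
                },
            ),
            seed=4,
        )
        f, p, used = sg.anova_by_sample_type(
            cohort, GeneSet("S", "d", truth.signature_genes)
        )
        assert p < 0.001 and len(used) == 3

    def test_anova_single_type_error(self, tiny_cohort, small_gene_set):
        tiny_cohort.annotations["sample_type"] = "primary"
        with pytest.raises(ValueError):
            sg.anova_by_sample_type(tiny_cohort, small_gene_set)
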