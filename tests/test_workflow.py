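import numpy as np
import pandas as pd
import pytest

from trajde.binning import BinnedExperiment
from trajde.glm import build_design
from trajde.workflow import (
    WorkflowConfig,
    cluster_trends,
    get_siggenes,
    p_vector,
    run_workflow,
    t_fit,
)

from conftest import two_path_meta


def _binned_from_truth(beta_by_gene, theta=10.0, n_bins=13, seed=0, offset_sd=0.3):
    """Pseudo-bulk counts simulated directly from the polynomial GLM."""
    rng = np.random.default_rng(seed)
    meta = two_path_meta(n_bins)
    design = build_design(meta, degree=3)
    offset = rng.normal(0, offset_sd, design.n_obs)
    meta["offset"] = offset
    meta["size"] = 100
    meta["total"] = 1000
    counts = np.zeros((len(beta_by_gene), design.n_obs), dtype=np.int64)
    for i, beta in enumerate(beta_by_gene):
        mu = np.exp(np.clip(design.X @ np.asarray(beta) + offset, -10, 14))
        counts[i] = rng.negative_binomial(theta, theta / (theta + mu))
    genes = np.array([f"g{i:03d}" for i in range(len(beta_by_gene))], dtype=object)
    return BinnedExperiment(counts=counts, gene_ids=genes, bin_meta=meta)


# term order: intercept, t, t2, t3, z[B], t:z[B], t2:z[B], t3:z[B]
FLAT = [3.5, 0, 0, 0, 0, 0, 0, 0]
LINEAR_TIME = [2.0, 0.5, 0, 0, 0, 0, 0, 0]
INTERACTION = [3.0, 0, 0, 0, 0, 0.5, 0, 0]

# Pseudo-bulk bins aggregate ~10^2 cells, so their NB dispersion is an order
# of magnitude above single-cell level; recovery checks use this regime.
PSEUDOBULK_THETA = 100.0

# Backward elimination retains each spurious term with probability ~alpha at
# the final step, so exact term-set cleanliness is bounded near (1-alpha)^7
# regardless of signal strength; recovery checks therefore run the stepwise
# stage at the stricter 0.01 per-term level.
RECOVERY_ALPHA = 0.01


class TestPVector:
    def test_flat_genes_pass_near_alpha_with_raw_p(self):
        """Screening without adjustment rejects flat genes at ~ alpha."""
        binned = _binned_from_truth([FLAT] * 800, seed=3)
        config = WorkflowConfig(theta=10.0, p_adjust="none")
        df, passed = p_vector(binned, config)
        assert len(passed) / len(df) == pytest.approx(0.05, abs=0.03)

    def test_strong_monotone_gene_screens_significant(self):
        binned = _binned_from_truth([LINEAR_TIME] * 20 + [FLAT] * 20, seed=4)
        df, passed = p_vector(binned, WorkflowConfig())
        strong = df.iloc[:20]
        assert (strong["p_value"] < 1e-3).mean() >= 0.95
        assert set(passed).issuperset(set(strong["gene"][strong["p_value"] < 1e-3]))

    def test_too_few_bins_raises_helpful_error(self):
        binned = _binned_from_truth([FLAT], n_bins=4)
        with pytest.raises(ValueError, match="degree"):
            p_vector(binned, WorkflowConfig(degree=3))

    def test_empty_pass_set_flows_through(self):
        binned = _binned_from_truth([FLAT] * 5, seed=5)
        config = WorkflowConfig(alpha_screen=1e-9)
        df, passed = p_vector(binned, config)
        assert passed == []
        refined = t_fit(binned, passed, config)
        assert refined.empty


class TestTFit:
    def test_linear_gene_recovers_time_term_without_interactions(self):
        binned = _binned_from_truth([LINEAR_TIME] * 30, theta=PSEUDOBULK_THETA, seed=6)
        config = WorkflowConfig(theta=PSEUDOBULK_THETA, alpha_step=RECOVERY_ALPHA)
        refined = t_fit(binned, list(binned.gene_ids), config)
        has_t = refined["selected_terms"].str.split(";").apply(lambda ts: "t" in ts)
        no_branch = ~refined["selected_terms"].str.contains("z", regex=False)
        assert (has_t & no_branch).mean() >= 0.9

    def test_interaction_gene_retains_interaction(self):
        binned = _binned_from_truth([INTERACTION] * 30, theta=PSEUDOBULK_THETA, seed=7)
        config = WorkflowConfig(theta=PSEUDOBULK_THETA, alpha_step=RECOVERY_ALPHA)
        refined = t_fit(binned, list(binned.gene_ids), config)
        kept = refined["selected_terms"].str.contains(":z[", regex=False)
        assert kept.mean() >= 0.9

    def test_flat_gene_forced_through_reaches_intercept_only(self):
        binned = _binned_from_truth([FLAT] * 40, seed=8)
        refined = t_fit(binned, list(binned.gene_ids), WorkflowConfig())
        reduced = refined[refined["selected_terms"] == ""]
        assert len(reduced) > 0
        assert (reduced["r_squared"] == 0.0).all()

    def test_elimination_bounded_by_term_count(self):
        # 7 non-intercept terms -> at most 7 eliminations; implied by
        # termination: selected_terms is always a subset of the full term set
        binned = _binned_from_truth([FLAT, LINEAR_TIME, INTERACTION], seed=9)
        refined = t_fit(binned, list(binned.gene_ids), WorkflowConfig())
        full_terms = {"t", "t2", "t3", "z[B]", "t:z[B]", "t2:z[B]", "t3:z[B]"}
        for terms in refined["selected_terms"]:
            assert set(t for t in terms.split(";") if t) <= full_terms


class TestGetSiggenes:
    @pytest.mark.parametrize(
        "r2,terms,expected",
        [
            (0.7, "t:z[B]", "branch-dependent"),
            (0.5, "t:z[B]", "not significant"),
            (0.8, "t;t2", "time-only"),
            (0.8, "z[B]", "branch-dependent"),
        ],
    )
    def test_partition_rules(self, r2, terms, expected):
        results = pd.DataFrame(
            {
                "gene": ["g"],
                "p_value": [0.001],
                "adjusted_p": [0.01],
                "converged": [True],
                "selected_terms": [terms],
                "term_pvalues": ["0.001"],
                "coefficients": ["intercept=1"],
                "r_squared": [r2],
            }
        )
        out = get_siggenes(results, rsq_threshold=0.6)
        assert out["classification"].iloc[0] == expected

    def test_raising_threshold_contracts_selection(self):
        rng = np.random.default_rng(0)
        results = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(50)],
                "p_value": rng.uniform(0, 0.04, 50),
                "adjusted_p": rng.uniform(0, 0.04, 50),
                "converged": True,
                "selected_terms": ["t"] * 50,
                "term_pvalues": ["0.01"] * 50,
                "coefficients": ["intercept=1;t=0.2"] * 50,
                "r_squared": rng.uniform(0, 1, 50),
            }
        )
        selected = [
            set(
                get_siggenes(results, thr)
                .query("classification != 'not significant'")["gene"]
            )
            for thr in (0.2, 0.5, 0.8)
        ]
        assert selected[0] >= selected[1] >= selected[2]


class TestWorkflowEndToEnd:
    def test_screen_and_gate_never_select_failing_genes(self, small_binned):
        config = WorkflowConfig()
        results = run_workflow(small_binned, config)
        sel = results[results["classification"] != "not significant"]
        assert (sel["adjusted_p"] <= config.alpha_screen).all()
        assert (sel["r_squared"] >= config.rsq_threshold).all()

    def test_parameter_recovery_from_known_models(self):
        """Simulating straight from the polynomial GLM at 26 bins with
        coefficients of magnitude >= 0.5, the workflow recovers the exact
        nonzero term set >= 85% of the time (stepwise at the stricter 0.01
        per-term level; see RECOVERY_ALPHA)."""
        rng = np.random.default_rng(123)
        truth_sets, betas = [], []
        candidates = {
            ("t",): [0, 0.5, 0, 0, 0, 0, 0, 0],
            ("t", "t:z[B]"): [0, 0.5, 0, 0, 0, -0.5, 0, 0],
            ("z[B]",): [0, 0, 0, 0, 2.0, 0, 0, 0],
            (): [0, 0, 0, 0, 0, 0, 0, 0],
        }
        names = list(candidates)
        for _ in range(120):
            key = names[rng.integers(len(names))]
            beta = np.array(candidates[key], dtype=float)
            beta[0] = 3.0
            truth_sets.append(set(key))
            betas.append(beta)
        binned = _binned_from_truth(
            betas, theta=PSEUDOBULK_THETA, seed=321, offset_sd=0.0
        )
        config = WorkflowConfig(theta=PSEUDOBULK_THETA, alpha_step=RECOVERY_ALPHA)
        refined = t_fit(binned, list(binned.gene_ids), config)
        hits = 0
        for truth, terms in zip(truth_sets, refined["selected_terms"]):
            got = set(t for t in terms.split(";") if t)
            hits += got == truth
        assert hits / len(truth_sets) >= 0.85

    def test_parallel_workers_match_serial(self, small_binned):
        serial = run_workflow(small_binned, WorkflowConfig(workers=1))
        parallel = run_workflow(small_binned, WorkflowConfig(workers=2))
        pd.testing.assert_frame_equal(serial, parallel)


class TestClusterTrends:
    def _results_with_curves(self, binned, coefs):
        rows = []
        for i, c in enumerate(coefs):
            rows.append(
                {
                    "gene": f"g{i}",
                    "p_value": 0.001,
                    "adjusted_p": 0.001,
                    "converged": True,
                    "selected_terms": "t",
                    "term_pvalues": "0.001",
                    "coefficients": f"intercept=1;t={c}",
                    "r_squared": 0.9,
                    "classification": "time-only",
                }
            )
        return pd.DataFrame(rows)

    def test_two_families_split_perfectly(self, small_binned):
        results = self._results_with_curves(small_binned, [1.0] * 5 + [-1.0] * 5)
        labels, trends = cluster_trends(results, small_binned, 2)
        up = set(labels.iloc[:5])
        down = set(labels.iloc[5:])
        assert len(up) == 1 and len(down) == 1 and up != down
        assert set(trends["cluster"]) == up | down

    def test_single_cluster_contains_all(self, small_binned):
        results = self._results_with_curves(small_binned, [1.0, 2.0, -1.0])
        labels, _ = cluster_trends(results, small_binned, 1)
        assert labels.nunique() == 1

    def test_constant_curve_handled_without_nan(self, small_binned):
        results = self._results_with_curves(small_binned, [1.0, 1.0, 0.0])
        labels, trends = cluster_trends(results, small_binned, 2)
        assert labels.notna().all()
        assert np.isfinite(trends["mean_trend"]).all()

    def test_too_many_clusters_rejected(self, small_binned):
        results = self._results_with_curves(small_binned, [1.0, -1.0])
        with pytest.raises(ValueError, match="exceeds"):
            cluster_trends(results, small_binned, 5)
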