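import numpy as np
import pytest

from sigrisk import (ExpressionMatrix, GeneSignature, assign_groups_quantile,
                     compute_pi, fit_or_weights, logrank_test, optimize_groups,
                     split_pvalue_bias_check, stratified_run, toggle_genes,
                     train_test_run)
from sigrisk.risk import default_min_group_size
from sigrisk.survival import cox_fit

from conftest import make_pi, random_censored


def expr_of(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(genes, samples, values)


class TestComputePI:
    def test_zero_betas_zero_pi(self):
        pi = compute_pi(expr_of(np.random.default_rng(0).normal(size=(3, 5))),
                        np.zeros(3))
        assert np.all(pi.pi == 0)

    def test_single_gene_identity(self):
        vals = np.array([[1.0, 2.0, 3.0]])
        pi = compute_pi(expr_of(vals), np.array([1.0]))
        assert pi.pi.tolist() == [1.0, 2.0, 3.0]

    def test_printed_formula_arithmetic(self):
        # beta = (1, -1), x = (2, 3) -> PI = -1
        pi = compute_pi(expr_of(np.array([[2.0], [3.0]])), np.array([1.0, -1.0]))
        assert pi.pi[0] == -1.0

    def test_linearity(self):
        rng = np.random.default_rng(6)
        ex = expr_of(rng.normal(size=(4, 10)))
        b1, b2 = rng.normal(size=4), rng.normal(size=4)
        assert np.allclose(compute_pi(ex, 2.5 * b1).pi,
                           2.5 * compute_pi(ex, b1).pi)
        assert np.allclose(compute_pi(ex, b1 + b2).pi,
                           compute_pi(ex, b1).pi + compute_pi(ex, b2).pi)

    def test_mismatched_betas_listed(self):
        ex = expr_of(np.zeros((2, 3)), genes=["a", "b"])
        with pytest.raises(ValueError, match="missing betas.*b"):
            compute_pi(ex, {"a": 1.0, "c": 2.0})


class TestFitOrWeights:
    def test_user_weights_pass_through(self, small_cohort):
        expr, clinical, _ = small_cohort
        sub = ExpressionMatrix(expr.probe_ids[:2], expr.sample_ids,
                               expr.values[:2])
        sig = GeneSignature([("SIG1", 0.5), ("SIG2", -0.2)])
        betas, fit, _ = fit_or_weights(sub, clinical, sig, mode="user")
        assert betas == {"SIG1": 0.5, "SIG2": -0.2}
        assert fit is None

    def test_user_mode_without_weights_rejected(self, small_cohort):
        expr, clinical, _ = small_cohort
        sig = GeneSignature([("SIG1", None)])
        sub = ExpressionMatrix(expr.probe_ids[:1], expr.sample_ids,
                               expr.values[:1])
        with pytest.raises(ValueError, match="weight"):
            fit_or_weights(sub, clinical, sig, mode="user")

    def test_cox_mode_delegates_to_cox_fit(self, small_cohort):
        expr, clinical, _ = small_cohort
        sub = ExpressionMatrix(expr.probe_ids[:5], expr.sample_ids,
                               expr.values[:5])
        sig = GeneSignature([(g, None) for g in sub.probe_ids])
        betas, fit, _ = fit_or_weights(sub, clinical, sig, mode="cox")
        ref = cox_fit(sub.values.T, clinical.time, clinical.event)
        assert np.allclose([betas[g] for g in sub.probe_ids], ref.beta)

    def test_zero_variance_gene_dropped_and_refit(self, small_cohort):
        expr, clinical, _ = small_cohort
        vals = np.vstack([expr.values[:3], np.full(len(expr.sample_ids), 5.0)])
        sub = ExpressionMatrix(["SIG1", "SIG2", "SIG3", "FLAT"],
                               expr.sample_ids, vals)
        sig = GeneSignature([(g, None) for g in sub.probe_ids])
        with pytest.warns(RuntimeWarning, match="FLAT"):
            betas, fit, used = fit_or_weights(sub, clinical, sig, mode="cox")
        assert "FLAT" not in betas and len(betas) == 3
        assert used.probe_ids == ["SIG1", "SIG2", "SIG3"]


class TestQuantileGroups:
    def run(self, n, k, seed=0):
        rng = np.random.default_rng(seed)
        pi = make_pi(rng.normal(size=n))
        time, event = random_censored(rng, n)
        return pi, assign_groups_quantile(pi, time, event, k=k)

    def test_even_median_split(self):
        pi, g = self.run(10, 2)
        assert g.group_sizes().tolist() == [5, 5]
        assert g.split_points[0] == pytest.approx(np.median(pi.pi))

    def test_equal_thirds(self):
        _, g = self.run(9, 3)
        assert g.group_sizes().tolist() == [3, 3, 3]

    def test_remainder_to_low_risk(self):
        _, g = self.run(9, 2)
        assert g.group_sizes().tolist() == [5, 4]

    @pytest.mark.parametrize("n,k", [(17, 3), (53, 4), (100, 2)])
    def test_sizes_differ_at_most_one_and_order_recovered(self, n, k):
        pi, g = self.run(n, k, seed=n)
        sizes = g.group_sizes()
        assert sizes.max() - sizes.min() <= 1
        # concatenating groups in label order recovers PI-sorted order
        order = np.argsort(pi.pi, kind="stable")
        assert np.all(np.diff(g.labels[order]) >= 0)

    def test_labels_monotone_in_pi(self):
        pi, g = self.run(40, 3, seed=4)
        srt = np.argsort(pi.pi, kind="stable")
        assert np.all(np.diff(g.labels[srt]) >= 0)

    def test_n_less_than_k(self):
        with pytest.raises(ValueError):
            self.run(3, 4)


class TestOptimizeGroups:
    def oracle_best_split(self, pi_vals, time, event, min_size):
        """Exhaustive scan with per-split logrank_test calls."""
        order = np.argsort(pi_vals, kind="stable")
        t, e = time[order], event[order]
        ps = np.sort(pi_vals)
        best, best_p = None, np.inf
        for b in range(min_size, len(t) - min_size + 1):
            if ps[b - 1] >= ps[b]:
                continue
            labels = (np.arange(len(t)) >= b).astype(int)
            p = logrank_test(t, e, labels).p_value
            if p < best_p:
                best, best_p = b, p
        return best, best_p

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(30, 120))
        pi_vals = rng.normal(size=n)
        time, event = random_censored(rng, n)
        pi = make_pi(pi_vals)
        g = optimize_groups(pi, time, event, k=2)
        b_oracle, p_oracle = self.oracle_best_split(
            pi_vals, time, event, default_min_group_size(n))
        assert g.scan["chosen"] == b_oracle
        assert g.separation.p_value == pytest.approx(p_oracle, abs=1e-10)

    def test_optimized_p_not_worse_than_median(self):
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            n = 60
            pi = make_pi(rng.normal(size=n))
            time, event = random_censored(rng, n)
            opt = optimize_groups(pi, time, event, k=2)
            med = assign_groups_quantile(pi, time, event, k=2)
            assert opt.separation.p_value <= med.separation.p_value + 1e-12

    def test_min_group_size_respected(self):
        rng = np.random.default_rng(50)
        n = 80
        pi = make_pi(rng.normal(size=n))
        time, event = random_censored(rng, n)
        g = optimize_groups(pi, time, event, k=2, min_group_size=15)
        assert g.group_sizes().min() >= 15

    def test_planted_split_recovered(self):
        # sharp two-population design: boundary near the plant
        rng = np.random.default_rng(9)
        n, m = 200, 80
        lam = np.where(np.arange(n) < m, 0.05, 0.5)
        time = rng.exponential(1 / lam)
        pi = make_pi(np.arange(n, dtype=float))
        g = optimize_groups(pi, time, np.ones(n, int), k=2)
        assert abs(g.scan["chosen"] - m) <= 5

    def test_tied_pi_never_straddles_boundary(self):
        rng = np.random.default_rng(3)
        n = 60
        pi_vals = np.repeat(rng.normal(size=n // 4), 4)  # heavy ties
        time, event = random_censored(rng, n)
        g = optimize_groups(make_pi(pi_vals), time, event, k=2)
        low = pi_vals[g.labels == 1]
        high = pi_vals[g.labels == 2]
        assert set(low) & set(high) == set()

    def test_k3_refinement_terminates_and_sizes_ok(self):
        rng = np.random.default_rng(13)
        n = 120
        pi = make_pi(rng.normal(size=n))
        time, event = random_censored(rng, n)
        g = optimize_groups(pi, time, event, k=3, min_group_size=10)
        assert g.k == 3
        assert g.group_sizes().min() >= 10
        assert g.notes["cycles"] <= 100
        assert g.separation.df == 2

    def test_infeasible_min_size(self):
        rng = np.random.default_rng(0)
        pi = make_pi(rng.normal(size=20))
        time, event = random_censored(rng, 20)
        with pytest.raises(ValueError):
            optimize_groups(pi, time, event, k=2, min_group_size=15)


class TestToggleGenes:
    sig = GeneSignature([("A", None), ("B", None), ("C", None)])

    def test_identity(self):
        out = toggle_genes(self.sig, ["A", "B", "C"])
        assert out.identifiers == ["A", "B", "C"]

    def test_subset(self):
        out = toggle_genes(self.sig, ["A", "C"])
        assert out.identifiers == ["A", "C"]

    def test_unknown_and_empty(self):
        with pytest.raises(ValueError, match="not in signature"):
            toggle_genes(self.sig, ["A", "Z"])
        with pytest.raises(ValueError, match="empty"):
            toggle_genes(self.sig, [])


class TestTrainTest:
    def test_generalization_on_simulated_truth(self):
        from sigrisk import SimConfig, simulate_dataset
        wins = 0
        for seed in range(10):
            cfg = SimConfig(n=240, betas=(1.0, -0.8), q_noise=0,
                            seed=300 + seed)
            expr, clinical, _ = simulate_dataset(cfg)
            sig = GeneSignature([(g, None) for g in expr.probe_ids])
            train = expr.sample_ids[:120]
            test = expr.sample_ids[120:]
            out = train_test_run(expr, clinical, sig, train, test)
            te = out["test"]
            cl_te = clinical.subset(test)
            high = te["labels"] == te["labels"].max()
            if cl_te.event[high].mean() > cl_te.event[~high].mean():
                wins += 1
        assert wins >= 8

    def test_overlap_rejected(self, small_cohort):
        expr, clinical, _ = small_cohort
        sig = GeneSignature([(g, None) for g in expr.probe_ids[:3]])
        sub = ExpressionMatrix(expr.probe_ids[:3], expr.sample_ids,
                               expr.values[:3])
        with pytest.raises(ValueError, match="overlap"):
            train_test_run(sub, clinical, sig, expr.sample_ids[:80],
                           expr.sample_ids[70:])

    def test_empty_test_rejected(self, small_cohort):
        expr, clinical, _ = small_cohort
        sig = GeneSignature([(g, None) for g in expr.probe_ids[:3]])
        sub = ExpressionMatrix(expr.probe_ids[:3], expr.sample_ids,
                               expr.values[:3])
        with pytest.raises(ValueError, match="test set is empty"):
            train_test_run(sub, clinical, sig, expr.sample_ids[:80], [])

    def test_small_train_set_warns_but_fits(self, small_cohort):
        expr, clinical, _ = small_cohort
        sig = GeneSignature([(g, None) for g in expr.probe_ids[:5]])
        sub = ExpressionMatrix(expr.probe_ids[:5], expr.sample_ids,
                               expr.values[:5])
        with pytest.warns(RuntimeWarning, match="few events"):
            out = train_test_run(sub, clinical, sig, expr.sample_ids[:8],
                                 expr.sample_ids[8:],
                                 grouping_cfg={"k": 2})
        assert out["fit"] is not None


class TestStratified:
    def build(self, seed=0, prognostic_stratum="A"):
        import pandas as pd
        from sigrisk import SimConfig, simulate_dataset
        rng = np.random.default_rng(seed)
        parts = []
        for label in ["A", "B", "C"]:
            betas = (1.2, -1.0) if label == prognostic_stratum else (0.0, 0.0)
            cfg = SimConfig(n=70, betas=betas, q_noise=0,
                            seed=seed * 10 + ord(label))
            ex, cl, _ = simulate_dataset(cfg)
            ids = [f"{label}{s}" for s in ex.sample_ids]
            parts.append((label, ids, ex, cl))
        genes = parts[0][2].probe_ids
        values = np.hstack([p[2].values for p in parts])
        ids = [i for p in parts for i in p[1]]
        expr = ExpressionMatrix(list(genes), ids, values)
        time = np.concatenate([p[3].time for p in parts])
        event = np.concatenate([p[3].event for p in parts])
        cov = pd.DataFrame({"grade": [p[0] for p in parts for _ in p[1]]})
        from sigrisk import ClinicalTable
        clinical = ClinicalTable(ids, time, event, cov)
        sig = GeneSignature([(g, None) for g in genes])
        return expr, clinical, sig

    def test_partition_into_three_results(self):
        expr, clinical, sig = self.build(seed=1)
        out = stratified_run(expr, clinical, sig, "grade")
        assert set(out["strata"]) == {"A", "B", "C"}
        assert len(out["summary"]) == 3

    def test_planted_heterogeneity(self):
        wins = 0
        for seed in range(10):
            expr, clinical, sig = self.build(seed=seed)
            out = stratified_run(expr, clinical, sig, "grade")
            ps = {s["stratum"]: s["logrank_p"] for s in out["summary"]}
            if ps["A"] < ps["B"] and ps["A"] < ps["C"]:
                wins += 1
        assert wins >= 8

    def test_small_stratum_skipped_with_note(self):
        expr, clinical, sig = self.build(seed=2)
        # drop stratum C to 5 samples so it falls below the floor
        keep = [s for s, g in zip(clinical.sample_ids,
                                  clinical.covariates["grade"])
                if g != "C"] + \
               [s for s, g in zip(clinical.sample_ids,
                                  clinical.covariates["grade"])
                if g == "C"][:5]
        expr2 = expr.subset_samples(keep)
        cl2 = clinical.subset(keep)
        out = stratified_run(expr2, cl2, sig, "grade", min_stratum_n=20)
        assert set(out["strata"]) == {"A", "B"}
        assert "C" in out["skipped"]

    def test_all_strata_too_small(self):
        expr, clinical, sig = self.build(seed=3)
        with pytest.raises(ValueError, match="minimum sample size"):
            stratified_run(expr, clinical, sig, "grade", min_stratum_n=500)

    def test_missing_covariate(self):
        expr, clinical, sig = self.build(seed=4)
        with pytest.raises(ValueError, match="no such covariate"):
            stratified_run(expr, clinical, sig, "stage")


class TestSplitBiasCheck:
    def test_nperm_floor(self):
        rng = np.random.default_rng(0)
        pi = make_pi(rng.normal(size=60))
        time, event = random_censored(rng, 60)
        with pytest.raises(ValueError, match="n_perm"):
            split_pvalue_bias_check(pi, time, event, n_perm=50)

    def test_prognostic_pi_detected(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(800 + seed)
            n = 300
            pi_vals = rng.normal(size=n)
            # HR = 3 across the PI median
            lam = np.where(pi_vals > np.median(pi_vals), 0.3, 0.1)
            time = rng.exponential(1 / lam)
            out = split_pvalue_bias_check(make_pi(pi_vals), time,
                                          np.ones(n, int), n_perm=100,
                                          seed=seed)
            hits += out["adjusted_p"] < 0.05
        assert hits >= 4

    def test_adjusted_p_larger_than_naive_under_null(self):
        rng = np.random.default_rng(5)
        n = 80
        pi = make_pi(rng.normal(size=n))
        time, event = random_censored(rng, n)
        out = split_pvalue_bias_check(pi, time, event, n_perm=200, seed=1)
        assert out["adjusted_p"] >= out["observed_min_p"]
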