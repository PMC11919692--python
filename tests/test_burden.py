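"""Covariate screening, burden regressions and partitioned metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cnvburden.burden import (
    constrained_base_burden,
    fit_burden,
    homogeneity_test,
    leave_one_out,
    partition_metrics,
    select_covariates,
)
from cnvburden.io_formats import CALL_COLUMNS
from cnvburden.simulate import null_sim_config, simulate_all

from conftest import make_samples


def _metric(samples, values):
    return pd.Series(values, index=samples["sample_id"])


def _calls(rows):
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


class TestSelectCovariates:
    def test_candidate_equal_to_raw_count_included(self):
        samples = make_samples(400, n_cases=200, seed=1)
        rng = np.random.default_rng(0)
        counts = pd.Series(rng.poisson(2.0, 400).astype(float), index=samples["sample_id"].to_numpy())
        # perfect count association; give it some case association too
        samples["pc6"] = counts.to_numpy() + 0.8 * samples["is_case"].to_numpy()
        cov = select_covariates(samples, counts)
        assert "pc6" in cov.selected

    def test_constant_candidate_excluded_with_note(self):
        samples = make_samples(100)
        samples["pc6"] = 1.0
        counts = pd.Series(1.0, index=samples["sample_id"].to_numpy())
        cov = select_covariates(samples, counts)
        assert "pc6" not in cov.selected
        note = cov.log.loc[cov.log["candidate"] == "pc6", "note"].iloc[0]
        assert note == "constant"

    def test_null_candidate_type_one_calibration(self):
        """A candidate independent of both outcomes is excluded in >=94%
        of 100 null replicates at alpha 0.05 (joint screen ~ 0.25%)."""
        samples = make_samples(300, n_cases=150, seed=2)
        rng = np.random.default_rng(7)
        counts = pd.Series(rng.poisson(1.5, 300).astype(float), index=samples["sample_id"].to_numpy())
        excluded = 0
        for _ in range(100):
            samples["pc6"] = rng.normal(0, 1, 300)
            cov = select_covariates(samples, counts, candidates=["pc6"])
            excluded += "pc6" not in cov.selected
        assert excluded >= 94

    def test_planted_structure_recovered(self):
        """PC7 with a batch shift tied to case mix, and LRRSD correlated
        with both call rate and case status, are both selected."""
        rng = np.random.default_rng(3)
        n = 2000
        samples = make_samples(n, n_cases=1000, seed=4)
        is_case = samples["is_case"].to_numpy(float)
        # dataset-like shift aligned with case composition
        samples["pc7"] = rng.normal(0, 1, n) + 0.4 * is_case
        samples["lrrsd"] = np.exp(-2.1 + 0.1 * is_case + rng.normal(0, 0.15, n))
        lam = 1.3 * np.exp(0.15 * samples["pc7"].to_numpy() + 2.0 * (np.log(samples["lrrsd"].to_numpy()) + 2.1))
        counts = pd.Series(rng.poisson(lam).astype(float), index=samples["sample_id"].to_numpy())
        cov = select_covariates(samples, counts)
        assert "pc7" in cov.selected and "lrrsd" in cov.selected


class TestFitBurden:
    COVS = ("pc1", "pc2", "pc3", "pc4", "pc5", "sex")

    def test_degenerate_metric_raises(self):
        samples = make_samples(100)
        with pytest.raises(ValueError, match="degenerate"):
            fit_burden(samples, _metric(samples, np.zeros(100)), self.COVS)

    def test_null_coverage_of_one(self):
        """Metric independent of case status: Wald CI covers OR=1 in
        roughly 95% of replicates (binomial 99.5% lower bound)."""
        rng = np.random.default_rng(11)
        samples = make_samples(400, n_cases=200, seed=5)
        cover = 0
        n_rep = 100
        for _ in range(n_rep):
            m = _metric(samples, rng.poisson(1.0, 400).astype(float))
            r = fit_burden(samples, m, self.COVS)
            cover += r.ci_lo <= 1.0 <= r.ci_hi
        assert cover >= stats.binom.ppf(0.005, n_rep, 0.95)

    def test_linear_model_reports_case_term(self):
        rng = np.random.default_rng(12)
        samples = make_samples(500, n_cases=250, seed=6)
        m = _metric(samples, rng.poisson(1.0, 500) + 0.5 * samples["is_case"].to_numpy())
        r = fit_burden(samples, m, self.COVS, model="linear")
        assert 0.2 < r.estimate < 0.8 and r.p < 0.05

    def test_scale_changes_unit_of_or(self):
        rng = np.random.default_rng(13)
        samples = make_samples(300, n_cases=150, seed=7)
        m = _metric(samples, rng.uniform(0, 3e5, 300))
        r1 = fit_burden(samples, m, self.COVS, scale=1e5)
        r2 = fit_burden(samples, m, self.COVS, scale=1.0)
        assert r1.estimate == pytest.approx(r2.estimate * 1e5, rel=1e-6)


class TestPartitions:
    def test_unknown_partition_rejected(self, tiny_bundle):
        samples = make_samples(10)
        with pytest.raises(ValueError, match="unknown partition"):
            partition_metrics(_calls([]), tiny_bundle, samples, partitions=("nope",))

    def test_pli_thresholding(self, tiny_bundle):
        """A CNV over a pLI=0.6 gene counts toward pLI>0.5 but not >0.995."""
        samples = make_samples(10)
        calls = _calls([("S0001", "chr1", 1_190_000, 1_260_000, "del", 1, 30, "consensus")])
        m = partition_metrics(calls, tiny_bundle, samples, partitions=("pli",))
        assert m.loc["S0001", "count_pli_gt_0.5"] == 1
        assert m.loc["S0001", "count_pli_gt_0.995"] == 0

    def test_noncoding_call_counts_noncoding_only(self, tiny_bundle):
        samples = make_samples(10)
        calls = _calls([("S0002", "chr1", 8_000_000, 8_060_000, "del", 1, 30, "consensus")])
        m = partition_metrics(calls, tiny_bundle, samples, partitions=("total", "coding"))
        assert m.loc["S0002", "noncoding_count"] == 1
        assert m.loc["S0002", "coding_count"] == 0

    def test_additivity_of_partitions(self):
        """coding+noncoding = total; size bins sum to total; del+dup = total."""
        sim = simulate_all(null_sim_config(31, 150, 150))
        from cnvburden.pipeline import prepare_callset
        ks, kc, _, _, _ = prepare_callset(sim.calls_a, sim.calls_b, sim.samples, sim.bundle, sim.baf)
        m = partition_metrics(kc, sim.bundle, ks, partitions=("total", "state", "size", "coding"))
        total = m["cnv_count"]
        assert np.allclose(m["coding_count"] + m["noncoding_count"], total)
        assert np.allclose(m["del_count"] + m["dup_count"], total)
        size_cols = [c for c in m.columns if c.startswith("count_") and ("kb" in c or "Mb" in c)]
        assert len(size_cols) == 4
        assert np.allclose(sum(m[c] for c in size_cols), total)

    def test_constrained_kb_hand_enumeration(self, tiny_bundle):
        """Hand-computed constrained-kb totals on a synthetic score track."""
        samples = make_samples(10)
        # raise scores >= 2 on chr1 windows [1,000,000, 1,020,000)
        s, e, sc = tiny_bundle.constraint["chr1"]
        sc = sc.copy()
        sc[1000:1020] = 2.5
        tiny_bundle.constraint["chr1"] = (s, e, sc)
        calls = _calls([
            ("S0001", "chr1", 1_010_000, 1_060_000, "del", 1, 25, "consensus"),  # 10 kb over cut
            ("S0002", "chr1", 990_000, 1_030_000, "dup", 3, 20, "consensus"),    # 20 kb over cut
        ])
        m = constrained_base_burden(calls, tiny_bundle, samples, phylop_cuts=(2.0,))
        assert m.loc["S0001", "constrained_kb_ge2_del"] == pytest.approx(10.0)
        assert m.loc["S0002", "constrained_kb_ge2_dup"] == pytest.approx(20.0)
        assert m.loc["S0001", "constrained_kb_ge2_dup"] == 0.0

    def test_uniform_low_scores_give_zero(self, tiny_bundle):
        samples = make_samples(10)
        calls = _calls([("S0001", "chr1", 1_000_000, 1_100_000, "del", 1, 40, "consensus")])
        m = constrained_base_burden(calls, tiny_bundle, samples, phylop_cuts=(1.0, 2.0))
        assert (m.loc["S0001"] == 0).all()

    def test_missing_constraint_chromosome_errors(self, tiny_bundle):
        samples = make_samples(10)
        calls = _calls([("S0001", "chr9", 0, 100_000, "del", 1, 40, "consensus")])
        with pytest.raises(ValueError, match="chr9"):
            constrained_base_burden(calls, tiny_bundle, samples)


class TestLeaveOneOut:
    COVS = ("pc1", "pc2", "sex")

    def test_four_datasets_four_results(self):
        samples = make_samples(400, n_cases=200, n_datasets=4, seed=8)
        rng = np.random.default_rng(20)
        m = _metric(samples, rng.poisson(1.0, 400).astype(float))
        results = leave_one_out(samples, m, self.COVS)
        assert len(results) == 4

    def test_needs_three_groups(self):
        samples = make_samples(100, n_datasets=2)
        m = _metric(samples, np.ones(100))
        with pytest.raises(ValueError, match=">=3"):
            leave_one_out(samples, m, self.COVS)

    def test_dropping_carrier_dataset_nulls_the_or(self):
        """All excess carriers in D1: holding out D1 gives OR near 1."""
        samples = make_samples(800, n_cases=400, n_datasets=4, seed=9)
        rng = np.random.default_rng(21)
        base = rng.binomial(1, 0.05, 800).astype(float)
        in_d1_case = (samples["dataset"] == "D1") & samples["is_case"]
        m_vals = base.copy()
        m_vals[in_d1_case.to_numpy() & (rng.random(800) < 0.5)] = 1.0
        m = _metric(samples, m_vals)
        results = {r.metric: r for r in leave_one_out(samples, m, self.COVS)}
        full = fit_burden(samples, m, self.COVS)
        assert full.or_ > 1.3
        assert abs(np.log(results["burden_loo_D1"].or_)) < abs(np.log(full.or_)) * 0.5


def test_excess_rate_recovers_planted_difference():
    """A planted +0.4 calls/sample case excess is recovered with a
    bootstrap CI covering the truth."""
    from cnvburden.burden import excess_rate

    rng = np.random.default_rng(40)
    samples = make_samples(1500, n_cases=750, seed=11)
    m = _metric(samples, rng.poisson(1.0 + 0.4 * samples["is_case"].to_numpy()).astype(float))
    est, (lo, hi) = excess_rate(samples, m, ("pc1", "pc2", "sex"), n_boot=100, seed=1)
    assert 0.2 < est < 0.6
    assert lo <= 0.4 <= hi


def test_homogeneity_interaction_null_calibration():
    """Country x burden interaction P is calibrated under the null."""
    rng = np.random.default_rng(30)
    rejections = 0
    n_rep = 60
    samples = make_samples(600, n_cases=300, seed=10)
    for _ in range(n_rep):
        m = _metric(samples, rng.poisson(1.0, 600).astype(float))
        p = homogeneity_test(samples, m, ("pc1", "pc2", "sex"), by="country")
        rejections += p < 0.05
    assert rejections <= stats.binom.ppf(0.995, n_rep, 0.05)
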