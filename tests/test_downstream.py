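"""Power analysis, Poisson overlap tests, enrichment, PRS and clinical
comparisons, checked against published counts and independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import gammaln

from cnvburden.config import PowerConfig
from cnvburden.downstream import (
    analytic_power,
    brainset_concentration,
    clinical_comparisons,
    contingency_comparison,
    geneset_enrichment,
    monte_carlo_power,
    percent_improvement,
    poisson_overlap_test,
    power_curve,
    prs_carrier_test,
)

from conftest import make_samples


class TestPower:
    CFG = PowerConfig()

    def test_rr_one_gives_alpha(self):
        alpha = self.CFG.alpha_family / self.CFG.n_tests
        p = analytic_power(0.01, 1.0 + 1e-12, self.CFG.n_cases, self.CFG.n_controls, alpha)
        assert p == pytest.approx(alpha, rel=0.01)

    def test_power_increases_with_rr_and_n(self):
        alpha = 2.5e-6
        ps = [analytic_power(0.005, rr, 2248, 3608, alpha) for rr in (2, 3, 5, 10)]
        assert all(b > a for a, b in zip(ps, ps[1:]))
        assert analytic_power(0.005, 3, 10_000, 10_000, alpha) > analytic_power(0.005, 3, 2248, 3608, alpha)

    def test_rr_star_strictly_decreasing_in_frequency(self):
        grid, rr_star = power_curve(self.CFG)
        att = rr_star[rr_star["attainable"]]
        assert len(att) == len(rr_star)
        vals = att.sort_values("frequency")["rr_star"].to_numpy()
        assert np.all(np.diff(vals) < 0)
        # solved to the target power
        for r in att.itertuples():
            p = analytic_power(r.frequency, r.rr_star, self.CFG.n_cases, self.CFG.n_controls,
                               self.CFG.alpha_family / self.CFG.n_tests)
            assert abs(p - self.CFG.target_power) < 1e-6

    def test_unattainable_reported_not_raised(self):
        cfg = PowerConfig(n_cases=20, n_controls=20, freq_grid=(1e-4,), rr_max=50.0)
        _, rr_star = power_curve(cfg)
        assert not rr_star["attainable"].iloc[0]
        assert np.isnan(rr_star["rr_star"].iloc[0])

    def test_analytic_matches_monte_carlo(self):
        """Analytic power within +/-0.02 of simulating the same z-test."""
        alpha = 2.5e-6
        for i, (f, rr) in enumerate([(0.01, 2.0), (0.01, 2.5), (0.01, 3.0)]):
            ana = analytic_power(f, rr, 2248, 3608, alpha)
            mc = monte_carlo_power(f, rr, 2248, 3608, alpha, n_rep=20_000, seed=i)
            assert abs(ana - mc) < 0.02, (f, rr, ana, mc)


class TestPoissonOverlap:
    def test_published_counts_reproduce_printed_p(self):
        """The de novo and LoF overlap tests round to the printed values."""
        assert round(poisson_overlap_test(9, 3.94), 2) == 0.02
        assert round(poisson_overlap_test(26, 17.30), 2) == 0.03

    def test_zero_observed_is_one(self):
        assert poisson_overlap_test(0, 5.0) == 1.0

    def test_matches_independent_log_space_summation(self):
        """Exact tail from scipy equals a log-space summation to 1e-12."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            lam = float(rng.uniform(0.5, 40))
            obs = int(rng.integers(1, 60))
            terms = [k * np.log(lam) - lam - gammaln(k + 1) for k in range(obs, obs + 400)]
            oracle = float(np.exp(terms - np.max(terms)).sum() * np.exp(np.max(terms)))
            assert poisson_overlap_test(obs, lam) == pytest.approx(oracle, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            poisson_overlap_test(-1, 3.0)
        with pytest.raises(ValueError):
            poisson_overlap_test(3, 0.0)


class TestBrainsetConcentration:
    def test_no_significant_gives_one(self):
        assert brainset_concentration([False] * 20, [True] * 5 + [False] * 15) == 1.0

    def test_all_and_only_brain_significant_matches_hypergeometric(self):
        """5 significant, all brain, 13 brain of 795: P equals the Fisher
        oracle computed from the hypergeometric point probabilities."""
        n, n_brain, n_sig = 795, 13, 5
        sig = [i < n_sig for i in range(n)]
        brain = [i < n_brain for i in range(n)]
        p = brainset_concentration(sig, brain)
        # oracle: two-sided Fisher by point-probability rule over the
        # hypergeometric distribution of (sig & brain)
        probs = [stats.hypergeom.pmf(k, n, n_brain, n_sig) for k in range(0, n_sig + 1)]
        pobs = probs[5]
        oracle = sum(v for v in probs if v <= pobs * (1 + 1e-7))
        assert p == pytest.approx(oracle, rel=1e-6)
        assert p < 1e-8

    def test_independence_gives_uniform_p(self):
        rng = np.random.default_rng(1)
        ps = []
        for _ in range(200):
            sig = rng.random(100) < 0.2
            brain = rng.random(100) < 0.3
            ps.append(brainset_concentration(sig, brain))
        # conservative (discrete) but not anti-conservative
        assert np.mean(np.array(ps) < 0.05) <= 0.07

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            brainset_concentration([], [])


class TestEnrichment:
    def test_collinear_geneset_flagged(self):
        samples = make_samples(300, n_cases=150, seed=1)
        rng = np.random.default_rng(2)
        total = pd.Series(rng.poisson(2.0, 300).astype(float), index=samples["sample_id"].to_numpy())
        counts = pd.DataFrame({"all_genes": total})
        res = geneset_enrichment(counts, samples, ("pc1", "sex"), total)
        assert res[0].flagged and "collinear" in res[0].note

    def test_empty_geneset_skipped(self):
        samples = make_samples(100)
        total = pd.Series(1.0, index=samples["sample_id"].to_numpy())
        counts = pd.DataFrame({"empty": pd.Series(0.0, index=samples["sample_id"].to_numpy())})
        res = geneset_enrichment(counts, samples, ("pc1", "sex"), total)
        assert res[0].flagged and "no impacted genes" in res[0].note

    def test_planted_enrichment_ranks_first(self):
        """The case-enriched geneset has the smallest P among 12 sets in
        >=9 of 10 seeded replicates."""
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            samples = make_samples(1000, n_cases=500, seed=seed)
            is_case = samples["is_case"].to_numpy(float)
            idx = samples["sample_id"].to_numpy()
            counts = {}
            for j in range(11):
                counts[f"null_{j}"] = rng.poisson(0.3, 1000).astype(float)
            counts["planted"] = rng.poisson(0.25 + 0.35 * is_case)
            counts = pd.DataFrame(counts, index=idx)
            total = pd.Series(rng.poisson(2.0, 1000) + counts.sum(axis=1).to_numpy(),
                              index=idx)
            res = geneset_enrichment(counts, samples, ("pc1", "sex"), total)
            best = min((r for r in res if np.isfinite(r.p)), key=lambda r: r.p)
            wins += best.geneset == "planted"
        assert wins >= 9


class TestPrs:
    def test_constant_carrier_flagged(self):
        samples = make_samples(100)
        out = prs_carrier_test(samples, [], "prs_ocd", ("pc1", "sex"))
        assert out["flagged"]

    def test_null_coverage(self):
        rng = np.random.default_rng(3)
        samples = make_samples(600, n_cases=300, seed=2)
        cover = 0
        n_rep = 60
        case_ids = samples.loc[samples["is_case"], "sample_id"].to_numpy()
        for _ in range(n_rep):
            carriers = rng.choice(case_ids, 25, replace=False)
            samples["prs_xdx"] = rng.normal(0, 1, 600)
            out = prs_carrier_test(samples, carriers, "prs_xdx", ("pc1", "sex"))
            cover += out["ci_lo"] <= 0.0 <= out["ci_hi"]
        assert cover >= stats.binom.ppf(0.005, n_rep, 0.95)

    def test_planted_shift_recovered(self):
        """A -0.45 SD carrier shift is estimated within [-0.6, -0.3]."""
        rng = np.random.default_rng(4)
        ests = []
        for seed in range(10):
            samples = make_samples(2000, n_cases=2000, seed=seed)
            case_ids = samples["sample_id"].to_numpy()
            carriers = rng.choice(case_ids, 60, replace=False)
            prs = rng.normal(0, 1, 2000)
            prs[np.isin(case_ids, carriers)] -= 0.45
            samples["prs_xdx"] = prs
            ests.append(prs_carrier_test(samples, carriers, "prs_xdx", ("pc1", "sex"))["estimate"])
        assert -0.6 < np.mean(ests) < -0.3


class TestClinical:
    def test_published_asd_table_reproduces_chi_square(self):
        """6/147 vs 6/1465 carriers: 4.1% vs 0.4%, Pearson chi2 ~ 24.3."""
        r = contingency_comparison("asd", "ndd_dup", 6, 147, 6, 1465, force_chi2=True)
        assert r.test == "chi2" and r.df == 1
        assert round(100 * 6 / 147, 1) == 4.1
        assert round(100 * 6 / 1465, 1) == 0.4
        assert r.statistic == pytest.approx(24.3, abs=0.15)

    def test_identical_rates_give_zero_statistic(self):
        r = contingency_comparison("x", "c", 10, 100, 100, 1000, force_chi2=True)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)

    def test_fisher_substituted_for_small_expected_counts(self):
        r = contingency_comparison("x", "c", 2, 10, 1, 500)
        assert r.test == "fisher"

    def test_percent_improvement_formula(self):
        out = percent_improvement([30, 20, 0], [15, 20, 5])
        assert out[0] == 50.0 and out[1] == 0.0 and np.isnan(out[2])

    def test_planted_treatment_response_difference_detected(self):
        """Carriers improving 16% vs 47% (SD ~30%) at n~850 with 15
        carriers: the pooled t-test is significant in >=9/10 replicates."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 850
            samples = make_samples(n, n_cases=n, seed=seed)
            samples["has_clinical"] = True
            carrier_ids = samples["sample_id"].iloc[:15].tolist()
            carrier = samples["sample_id"].isin(carrier_ids).to_numpy()
            pre = np.clip(np.round(rng.normal(27, 4.5, n)), 16, 40)
            impr = np.clip(rng.normal(np.where(carrier, 0.16, 0.47), 0.30), -0.5, 1.0)
            samples["ybocs_pre"] = pre
            samples["ybocs_post"] = np.clip(np.round(pre * (1 - impr)), 0, 40)
            res = clinical_comparisons(samples, {"NDD deletion": carrier_ids})
            t_res = [r for r in res if r.test == "ttest"][0]
            hits += t_res.p < 0.05
            assert t_res.n_carrier == 15
        assert hits >= 9

    def test_missing_ybocs_excluded(self):
        samples = make_samples(50, n_cases=50)
        samples["has_clinical"] = True
        samples["ybocs_pre"] = np.nan
        samples["ybocs_post"] = np.nan
        res = clinical_comparisons(samples, {"c": samples["sample_id"].iloc[:5].tolist()})
        t_res = [r for r in res if r.test == "ttest"][0]
        assert np.isnan(t_res.p) and t_res.n_carrier == 0
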