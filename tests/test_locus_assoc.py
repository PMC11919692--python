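"""Clumping, exact stratified CMH, BH-FDR and permutation machinery."""

import itertools
from collections import defaultdict

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cnvburden.io_formats import CALL_COLUMNS
from cnvburden.locus_assoc import (
    LocusUnit,
    bh_fdr,
    clump_units,
    cmh_exact,
    cmh_exact_tables,
    exclude_inflation_clusters,
    permutation_lambda,
    recurrence_test,
)
from cnvburden.simulate import null_sim_config, simulate_all
from cnvburden.pipeline import prepare_callset

from conftest import make_samples


def _calls(rows):
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


class _GeneBundle:
    """Minimal object with .genes / .probes for clump_units."""

    def __init__(self, genes, probes=None):
        self.genes = genes
        self.probes = probes or {}


def _genes(spans):
    return pd.DataFrame(
        [(g, "chr1", s, e, 0.5, 0.1, False, False, "") for g, s, e in spans],
        columns=["gene_id", "chrom", "start", "end", "pli", "pnull",
                 "haplosensitive", "triplosensitive", "genesets"],
    )


class TestClumping:
    def test_fully_shared_genes_merge(self):
        genes = _genes([("g1", 100_000, 150_000), ("g2", 160_000, 200_000)])
        rows = [(f"S{i}", "chr1", 90_000, 210_000, "del", 1, 30, "consensus") for i in range(3)]
        units = clump_units(_calls(rows), _GeneBundle(genes), make_samples(10), "gene", "del")
        assert len(units) == 1 and units[0].members == ("g1", "g2")

    def test_disjoint_carriers_stay_separate(self):
        genes = _genes([("g1", 100_000, 150_000), ("g2", 300_000, 350_000)])
        rows = [("S1", "chr1", 90_000, 160_000, "del", 1, 30, "consensus"),
                ("S2", "chr1", 290_000, 360_000, "del", 1, 30, "consensus")]
        units = clump_units(_calls(rows), _GeneBundle(genes), make_samples(10), "gene", "del")
        assert len(units) == 2

    def test_five_gene_fixture_hand_run(self):
        """Call sets designed so the >50% sharing rule merges g1-g2 and
        g3-g4 but leaves g5 alone (hand-run of the merge rule):
        J12=6/9, J23=2/14, J34=6/10, J45=2/11."""
        spans = [(f"g{i+1}", 100_000 + 200_000 * i, 150_000 + 200_000 * i) for i in range(5)]
        genes = _genes(spans)
        rows = []
        sid = itertools.count()

        def span_calls(n, lo_gene, hi_gene):
            for _ in range(n):
                s = spans[lo_gene][1] - 10_000
                e = spans[hi_gene][2] + 10_000
                rows.append((f"S{next(sid):03d}", "chr1", s, e, "del", 1, 30, "consensus"))

        span_calls(1, 0, 0)   # n_1 = 1
        span_calls(6, 0, 1)   # n_12 = 6
        span_calls(2, 1, 2)   # n_23 = 2
        span_calls(6, 2, 3)   # n_34 = 6
        span_calls(2, 3, 4)   # n_45 = 2
        span_calls(1, 4, 4)   # n_5 = 1
        units = clump_units(_calls(rows), _GeneBundle(genes), make_samples(30), "gene", "del")
        members = sorted(tuple(u.members) for u in units)
        assert members == [("g1", "g2"), ("g3", "g4"), ("g5",)]

    def test_clumping_invariant_to_call_order(self):
        sim = simulate_all(null_sim_config(41, 120, 120))
        ks, kc, _, _, _ = prepare_callset(sim.calls_a, sim.calls_b, sim.samples, sim.bundle, sim.baf)
        u1 = clump_units(kc, sim.bundle, ks, "gene", "del")
        perm = kc.sample(frac=1.0, random_state=3).reset_index(drop=True)
        u2 = clump_units(perm, sim.bundle, ks, "gene", "del")
        key = lambda us: [(u.unit_id, u.members, u.carriers) for u in us]
        assert key(u1) == key(u2)

    def test_breakpoint_units_cover_calls(self):
        sim = simulate_all(null_sim_config(42, 100, 100))
        ks, kc, _, _, _ = prepare_callset(sim.calls_a, sim.calls_b, sim.samples, sim.bundle, sim.baf)
        units = clump_units(kc, sim.bundle, ks, "breakpoint", "del")
        covered_carriers = set()
        for u in units:
            covered_carriers |= set(u.carriers)
        dels = kc[kc["state"] == "del"]
        # every deletion carrier with >=1 probe-covered call appears in a unit
        assert set(dels["sample_id"]) == covered_carriers


class TestCmhExact:
    def test_single_stratum_equals_fisher(self):
        """200 random 2x2 tables: exact CMH == two-sided Fisher to 1e-10."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            n1 = int(rng.integers(1, 30))
            n2 = int(rng.integers(1, 30))
            m = int(rng.integers(0, n1 + n2 + 1))
            a = int(rng.integers(max(0, m - n2), min(m, n1) + 1))
            r = cmh_exact_tables([(a, m, n1, n2)])
            pf = stats.fisher_exact([[a, m - a], [n1 - a, n2 - (m - a)]])[1]
            assert abs(r.p - pf) < 1e-10

    def test_two_strata_match_brute_force_enumeration(self):
        """Margins <= 6: P matches exhaustive convolution of outcome pairs
        aggregated by the CMH statistic T."""
        rng = np.random.default_rng(1)

        def brute(tables, t_obs):
            supports = [range(max(0, m - n2), min(m, n1) + 1) for _, m, n1, n2 in tables]
            pT = defaultdict(float)
            for combo in itertools.product(*supports):
                lp = 1.0
                for (_, m, n1, n2), t in zip(tables, combo):
                    lp *= stats.hypergeom.pmf(t, n1 + n2, m, n1)
                pT[sum(combo)] += lp
            tot = sum(pT.values())
            pobs = pT[t_obs]
            return sum(v for v in pT.values() if v <= pobs * (1 + 1e-9)) / tot

        for _ in range(60):
            tabs = []
            for _ in range(2):
                n1 = int(rng.integers(1, 7))
                n2 = int(rng.integers(1, 7))
                m = int(rng.integers(0, min(6, n1 + n2) + 1))
                a = int(rng.integers(max(0, m - n2), min(m, n1) + 1))
                tabs.append((a, m, n1, n2))
            r = cmh_exact_tables(tabs)
            assert r.p == pytest.approx(brute(tabs, sum(t[0] for t in tabs)), abs=1e-12)

    def test_zero_carriers_p_one_or_missing(self):
        r = cmh_exact_tables([(0, 0, 10, 10), (0, 0, 5, 5)])
        assert r.p == 1.0 and np.isnan(r.or_cmh)

    def test_stratum_order_invariance(self):
        tabs = [(2, 4, 20, 25), (1, 3, 15, 18), (0, 1, 9, 12), (1, 1, 6, 7)]
        r1 = cmh_exact_tables(tabs)
        r2 = cmh_exact_tables(tabs[::-1])
        assert r1.p == pytest.approx(r2.p, abs=1e-14)
        assert r1.or_cmh == pytest.approx(r2.or_cmh, rel=1e-9)

    def test_label_swap_inverts_or_keeps_p(self):
        tabs = [(3, 5, 50, 60), (1, 4, 40, 45)]
        swapped = [(m - a, m, n2, n1) for a, m, n1, n2 in tabs]
        r1, r2 = cmh_exact_tables(tabs), cmh_exact_tables(swapped)
        assert r1.p == pytest.approx(r2.p, abs=1e-14)
        assert r1.or_cmh * r2.or_cmh == pytest.approx(1.0, rel=1e-8)

    def test_double_tail_convention(self):
        """Twice-the-smaller-tail is a valid P in (0,1] and coincides with
        the point-probability rule on symmetric (n1 == n2) tables, where
        equally-likely outcomes pair across the two tails."""
        rng = np.random.default_rng(9)
        for _ in range(50):
            n1 = int(rng.integers(2, 20))
            m = int(rng.integers(1, 2 * n1))
            a = int(rng.integers(max(0, m - n1), min(m, n1) + 1))
            r1 = cmh_exact_tables([(a, m, n1, n1)], two_sided="point_prob")
            r2 = cmh_exact_tables([(a, m, n1, n1)], two_sided="double_tail")
            assert 0 < r2.p <= 1.0
            assert r1.p == pytest.approx(r2.p, abs=1e-12)

    def test_unit_interface_matches_table_interface(self):
        samples = make_samples(200, n_cases=100, seed=1)
        carriers = tuple(samples["sample_id"].iloc[[1, 5, 9, 100, 150]])
        unit = LocusUnit("u1", "del", "chr1", 0, 50_000, ("g1",), carriers)
        r = cmh_exact(unit, samples)
        assert r.n_carriers == 5 and 0 < r.p <= 1


class TestBhFdr:
    def test_single_p(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_step_up(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_empty(self):
        assert bh_fdr([]).size == 0


def _sim_units(seed, n=300, state="del"):
    sim = simulate_all(null_sim_config(seed, n, n))
    ks, kc, _, _, _ = prepare_callset(sim.calls_a, sim.calls_b, sim.samples, sim.bundle, sim.baf)
    return clump_units(kc, sim.bundle, ks, "gene", state), ks


class TestPermutationLambda:
    def test_nperm_floor_enforced(self):
        units, ks = _sim_units(51, 80)
        with pytest.raises(ValueError, match="n_perm"):
            permutation_lambda(units, ks, n_perm=50)

    def test_self_null_lambda_near_one(self):
        """Replacing observed labels by within-stratum permutations gives
        lambda centred on 1 (median over shuffle seeds within 0.1)."""
        units, ks = _sim_units(52, 400)
        rng = np.random.default_rng(0)
        lams = []
        for _ in range(12):
            shuffled = ks.copy()
            for stratum in shuffled["stratum"].unique():
                idx = shuffled.index[shuffled["stratum"] == stratum]
                vals = shuffled.loc[idx, "is_case"].to_numpy()
                shuffled.loc[idx, "is_case"] = rng.permutation(vals)
            lams.append(permutation_lambda(units, shuffled, 100, seed=1).lambda_)
        assert abs(np.median(lams) - 1.0) <= 0.15

    def test_reproducible_given_seed(self):
        units, ks = _sim_units(53, 400)
        l1 = permutation_lambda(units, ks, 100, seed=9).lambda_
        l2 = permutation_lambda(units, ks, 100, seed=9).lambda_
        assert np.isfinite(l1) and l1 == l2


class TestExclusion:
    def _balanced_units(self, samples, n_units=30, seed=0):
        """Mixed-class units (2 cases + 2 controls) carry no batch signature."""
        rng = np.random.default_rng(seed)
        units = []
        cases = samples.loc[samples["is_case"], "sample_id"].to_numpy()
        ctrls = samples.loc[~samples["is_case"], "sample_id"].to_numpy()
        for i in range(n_units):
            carriers = tuple(rng.choice(cases, 2, replace=False)) + tuple(rng.choice(ctrls, 2, replace=False))
            units.append(LocusUnit(f"u{i}", "del", "chr1", i * 100_000, i * 100_000 + 50_000,
                                   (f"g{i}",), carriers))
        return units

    def test_no_inflation_no_exclusions(self):
        samples = make_samples(400, n_cases=200, seed=2)
        units = self._balanced_units(samples)
        excluded, final = exclude_inflation_clusters(units, samples, 100, seed=0,
                                                     lambda_threshold=1.5)
        assert excluded == []

    def test_uniform_case_excess_not_excluded(self):
        """Genuine case excess spread over all datasets fails the
        concentration condition: lambda stays high, nothing excluded."""
        samples = make_samples(400, n_cases=200, n_datasets=4, seed=3)
        cases = samples.loc[samples["is_case"], "sample_id"].to_numpy()
        ctrls = samples.loc[~samples["is_case"], "sample_id"].to_numpy()
        rng = np.random.default_rng(1)
        units = []
        for i in range(25):
            carriers = tuple(rng.choice(cases, 5, replace=False)) + tuple(rng.choice(ctrls, 1))
            units.append(LocusUnit(f"u{i}", "del", "chr1", i * 100_000, i * 100_000 + 50_000,
                                   (f"g{i}",), carriers))
        with pytest.warns(UserWarning, match="no qualifying"):
            excluded, final = exclude_inflation_clusters(units, samples, 100, seed=0)
        assert excluded == []
        assert final.lambda_ > 1.05


class TestRecurrence:
    def test_zero_deletions(self):
        samples = make_samples(100)
        r = recurrence_test([], samples, n_perm=100, seed=0)
        assert r.observed == 0 and r.empirical_p == 1.0

    def test_empirical_p_floor(self):
        units, ks = _sim_units(54, 150)
        r = recurrence_test(units, ks, n_perm=199, seed=2)
        assert r.empirical_p >= 1.0 / 200.0

    def test_reproducible_and_seed_sensitive(self):
        units, ks = _sim_units(55, 150)
        r1 = recurrence_test(units, ks, n_perm=199, seed=3)
        r2 = recurrence_test(units, ks, n_perm=199, seed=3)
        assert r1.empirical_p == r2.empirical_p and r1.observed == r2.observed

    def test_planted_recurrent_case_deletions_detected(self):
        """Recurrent case-only doubleton deletions give small P: the
        statistic counts units with >=2 case carriers, so 8 case-only
        pairs far exceed the ~25% per-unit null rate."""
        samples = make_samples(800, n_cases=400, seed=4)
        cases = samples.loc[samples["is_case"], "sample_id"].to_numpy()
        rng = np.random.default_rng(5)
        units = []
        for i in range(8):  # planted recurrent case-only pairs
            carriers = tuple(rng.choice(cases, 2, replace=False))
            units.append(LocusUnit(f"risk{i}", "del", "chr1", i * 100_000, i * 100_000 + 50_000,
                                   (f"g{i}",), carriers))
        sid = samples["sample_id"].to_numpy()
        for i in range(40):  # background singleton units carry no signal
            carriers = (sid[rng.integers(0, len(sid))],)
            units.append(LocusUnit(f"bg{i}", "del", "chr1", (i + 10) * 100_000,
                                   (i + 10) * 100_000 + 50_000, (f"h{i}",), carriers))
        r = recurrence_test(units, samples, n_perm=499, seed=6)
        assert r.observed == 8
        assert r.empirical_p <= 0.02
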