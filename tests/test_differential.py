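"""Differential testing: Mann-Whitney (exact + asymptotic), the subject-
balanced bootstrap, m_total-inflated Benjamini-Hochberg, the logistic
age x abundance interaction, LOESS trajectories and covariate balance."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
from hypothesis import given, settings
from hypothesis import strategies as st_h
from statsmodels.stats.multitest import multipletests

from spikescan.differential import (
    BootstrapConfig,
    DifferentialError,
    bootstrap_balanced_p,
    covariate_balance,
    fdr_adjust,
    loess_trajectory,
    mann_whitney,
)
from spikescan.differential import age_interaction_test as run_age_interaction
from spikescan.differential import test_all_taxa as run_all_taxa


def brute_force_mw_p(x, y):
    """Exact two-sided p by enumerating all group assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    obs_u = sum(1 for xi in x for yj in y if xi > yj)
    us = []
    for comb in itertools.combinations(range(len(pooled)), n1):
        xs = pooled[list(comb)]
        ys = np.delete(pooled, list(comb))
        us.append(sum(1 for xi in xs for yj in ys if xi > yj))
    us = np.array(us)
    mu = n1 * (len(pooled) - n1) / 2
    return float(np.mean(np.abs(us - mu) >= abs(obs_u - mu) - 1e-12))


class TestMannWhitney:
    def test_small_exact_example(self):
        assert mann_whitney([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_identical_groups_p_one(self):
        assert mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(DifferentialError):
            mann_whitney([], [1.0])

    @settings(deadline=None, max_examples=40)
    @given(st_h.integers(0, 2**31 - 1))
    def test_exact_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = int(rng.integers(2, 7)), int(rng.integers(2, 7))
        vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))  # tie-free
        x, y = vals[:n1], vals[n1:]
        assert mann_whitney(x, y) == pytest.approx(brute_force_mw_p(x, y))

    def test_large_sample_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.normal(size=30)
            y = rng.normal(0.4, size=40)
            ours = mann_whitney(x, y)
            ref = st.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
            assert ours == pytest.approx(ref, rel=1e-9)

    def test_tied_data_matches_scipy(self):
        rng = np.random.default_rng(6)
        x = rng.integers(0, 5, size=25).astype(float)
        y = rng.integers(0, 5, size=30).astype(float)
        ref = st.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert mann_whitney(x, y) == pytest.approx(ref, rel=1e-9)

    def test_null_rejection_rate_nominal(self):
        rng = np.random.default_rng(7)
        rejections = sum(
            mann_whitney(rng.normal(size=50), rng.normal(size=50)) < 0.05 for _ in range(400)
        )
        se = np.sqrt(0.05 * 0.95 / 400)
        assert abs(rejections / 400 - 0.05) < 3 * se


def _make_subject_data(rng, n_case_subj, n_ctrl_subj, samples_per_subject, subject_sd=0.0):
    values, labels, subjects = [], [], []
    for g, n_subj in (("case", n_case_subj), ("control", n_ctrl_subj)):
        for i in range(n_subj):
            sid = f"{g}{i}"
            eff = rng.normal(0, subject_sd)
            k = samples_per_subject if np.isscalar(samples_per_subject) else samples_per_subject[g][i]
            for _ in range(k):
                values.append(eff + rng.normal())
                labels.append(g)
                subjects.append(sid)
    return np.array(values), np.array(labels), np.array(subjects)


class TestBootstrapBalanced:
    def test_one_sample_per_subject_reduces_to_plain_test(self):
        rng = np.random.default_rng(8)
        for n1, n2 in [(5, 6), (20, 25)]:
            v, l, s = _make_subject_data(rng, n1, n2, 1)
            cfg = BootstrapConfig(iterations=17, per_subject_k=1, seed=3)
            assert bootstrap_balanced_p(v, l, s, cfg) == pytest.approx(
                mann_whitney(v[l == "case"], v[l == "control"])
            )

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        v, l, s = _make_subject_data(rng, 10, 10, 3, subject_sd=0.5)
        cfg = BootstrapConfig(iterations=50, seed=11)
        assert bootstrap_balanced_p(v, l, s, cfg) == bootstrap_balanced_p(v, l, s, cfg)

    def test_group_without_subjects_rejected(self):
        v = np.array([1.0, 2.0])
        l = np.array(["case", "case"])
        s = np.array(["a", "b"])
        with pytest.raises(DifferentialError):
            bootstrap_balanced_p(v, l, s, BootstrapConfig())

    def test_invariant_to_identical_subject_duplication(self):
        # duplicating every subject's sample set identically leaves the
        # per-subject resampling distribution unchanged
        rng = np.random.default_rng(10)
        diffs = []
        for rep in range(20):
            v, l, s = _make_subject_data(rng, 12, 12, 2, subject_sd=0.5)
            v2 = np.concatenate([v, v])
            l2 = np.concatenate([l, l])
            s2 = np.concatenate([s, s])
            cfg = BootstrapConfig(iterations=200, seed=rep)
            diffs.append(
                bootstrap_balanced_p(v, l, s, cfg) - bootstrap_balanced_p(v2, l2, s2, cfg)
            )
        assert abs(np.mean(diffs)) < 0.03

    def test_balancing_controls_oversampled_subject(self):
        # one case subject sampled 12x as often, strong subject effects, no
        # group effect: the plain all-samples test is anticonservative, the
        # balanced bootstrap stays near nominal
        rng = np.random.default_rng(12)
        plain_rej, balanced_rej, n_rep = 0, 0, 150
        for rep in range(n_rep):
            sps = {"case": [12] + [1] * 9, "control": [1] * 10}
            v, l, s = _make_subject_data(rng, 10, 10, sps, subject_sd=1.0)
            plain_rej += mann_whitney(v[l == "case"], v[l == "control"]) < 0.05
            cfg = BootstrapConfig(iterations=60, seed=rep)
            balanced_rej += bootstrap_balanced_p(v, l, s, cfg) < 0.05
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert plain_rej / n_rep > 0.05 + 3 * se
        assert balanced_rej / n_rep < 0.05 + 3 * se


class TestFdr:
    def test_single_p_identity(self):
        assert fdr_adjust([0.01], 1).tolist() == [0.01]

    def test_hand_worked_step_up(self):
        assert fdr_adjust([0.01, 0.02, 0.03], 3) == pytest.approx([0.03, 0.03, 0.03])

    def test_m_total_inflation(self):
        assert fdr_adjust([0.001], 100) == pytest.approx([0.1])

    def test_m_total_smaller_than_list_rejected(self):
        with pytest.raises(DifferentialError):
            fdr_adjust([0.1, 0.2], 1)

    @settings(deadline=None, max_examples=40)
    @given(st_h.integers(0, 2**31 - 1))
    def test_matches_statsmodels_without_inflation(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(int(rng.integers(1, 30)))
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(fdr_adjust(p, len(p)), ref)

    @settings(deadline=None, max_examples=40)
    @given(st_h.integers(0, 2**31 - 1))
    def test_inflation_equals_padding_with_ones(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(1, 15))
        m = k + int(rng.integers(0, 20))
        p = rng.random(k)
        padded = np.concatenate([p, np.ones(m - k)])
        ref = multipletests(padded, method="fdr_bh")[1][:k]
        assert np.allclose(fdr_adjust(p, m), ref)

    def test_adjusted_at_least_raw_and_monotone(self):
        rng = np.random.default_rng(13)
        p = rng.random(50)
        adj = fdr_adjust(p, 120)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestAllTaxa:
    def test_alpha_zero_empty_significant_set(self, processed):
        from spikescan.tables import apply_cutoff

        kept, m_total = apply_cutoff(processed["rel_species"], 0.01)
        res = run_all_taxa(kept, processed["metadata"], BootstrapConfig(iterations=5, seed=1), m_total, alpha=0.0)
        assert not res["significant"].any()
        assert ((res["fdr_p"] + 1e-12) >= res["boot_p"]).all()
        assert res["raw_p"].between(0, 1).all()

    def test_results_independent_of_taxon_order(self, processed):
        from spikescan.tables import RelativeAbundanceTable, apply_cutoff

        rel = processed["rel_species"]
        rev_full = RelativeAbundanceTable(
            rel.fractions.iloc[::-1], rel.lineage.iloc[::-1], rel.rarefaction_depth
        )
        kept, m_total = apply_cutoff(rel, 0.01)
        rev, _ = apply_cutoff(rev_full, 0.01)
        cfg = BootstrapConfig(iterations=20, seed=4)
        a = run_all_taxa(kept, processed["metadata"], cfg, m_total).set_index("taxon")["boot_p"]
        b = run_all_taxa(rev, processed["metadata"], cfg, m_total).set_index("taxon")["boot_p"]
        pd.testing.assert_series_equal(a.sort_index(), b.sort_index())


class TestAgeInteraction:
    def test_null_p_uniform(self):
        rng = np.random.default_rng(14)
        ps = []
        for _ in range(200):
            n = 150
            a = rng.lognormal(-3, 1, n)
            t = rng.uniform(150, 800, n)
            lab = np.where(rng.random(n) < 0.4, "case", "control")
            if len(set(lab)) < 2:
                continue
            ps.append(run_age_interaction(a, t, lab)["p"])
        assert st.kstest(ps, "uniform").pvalue > 0.01

    def test_detects_label_dependent_age_slope(self):
        rng = np.random.default_rng(15)
        hits = 0
        for _ in range(20):
            n = 200
            t = rng.uniform(150, 800, n)
            lab = np.where(rng.random(n) < 0.4, "case", "control")
            slope = np.where(lab == "case", 0.004, -0.004)
            a = 0.5 + slope * (t - 475) + rng.normal(0, 0.3, n)
            hits += run_age_interaction(a, t, lab)["p"] < 0.001
        assert hits >= 18

    def test_constant_abundance_rejected(self):
        with pytest.raises(DifferentialError, match="constant abundance"):
            run_age_interaction([0.1] * 10, range(10), ["case", "control"] * 5)

    def test_single_label_rejected(self):
        with pytest.raises(DifferentialError):
            run_age_interaction(np.arange(10.0), range(10), ["case"] * 10)


class TestLoess:
    def test_constant_signal_recovered(self):
        rng = np.random.default_rng(16)
        t = rng.uniform(0, 100, 80)
        res = loess_trajectory(t, np.full(80, 0.3), ["case"] * 40 + ["control"] * 40)
        assert np.allclose(res["fit"], 0.3, atol=1e-9)
        assert (res["se"] < 1e-6).all()

    def test_noiseless_line_recovered_at_interior(self):
        t = np.linspace(0, 100, 60)
        y = 0.002 * t + 0.05
        res = loess_trajectory(t, y, ["case"] * 60, span=0.5)
        interior = res[(res["age_days"] > 10) & (res["age_days"] < 90)]
        assert np.allclose(interior["fit"], 0.002 * interior["age_days"] + 0.05, atol=1e-6)

    def test_grid_covers_full_age_range(self):
        rng = np.random.default_rng(17)
        t = rng.uniform(120, 800, 50)
        res = loess_trajectory(t, rng.random(50), ["case"] * 50)
        assert res["age_days"].min() == pytest.approx(t.min())
        assert res["age_days"].max() == pytest.approx(t.max())

    def test_invalid_span_rejected(self):
        with pytest.raises(DifferentialError):
            loess_trajectory(np.arange(20.0), np.arange(20.0), ["case"] * 20, span=1.5)


class TestCovariateBalance:
    def test_perfectly_balanced_2x2(self):
        cov = pd.DataFrame(
            {"group": ["case"] * 20 + ["control"] * 20, "delivery_mode": (["a"] * 10 + ["b"] * 10) * 2}
        )
        res = covariate_balance(cov)
        row = res[res["covariate"] == "delivery_mode"].iloc[0]
        assert row["chi2"] == pytest.approx(0.0)
        assert row["p"] == pytest.approx(1.0)

    def test_complete_confounding_detected(self):
        cov = pd.DataFrame(
            {"group": ["case"] * 30 + ["control"] * 30, "delivery_mode": ["a"] * 30 + ["b"] * 30}
        )
        res = covariate_balance(cov)
        assert res[res["covariate"] == "delivery_mode"]["p"].iloc[0] < 0.001

    def test_single_level_covariate_is_na(self):
        cov = pd.DataFrame({"group": ["case", "control"] * 10, "delivery_mode": ["a"] * 20})
        res = covariate_balance(cov)
        assert np.isnan(res[res["covariate"] == "delivery_mode"]["p"].iloc[0])

    def test_generator_defaults_are_balanced(self, cohort):
        res = covariate_balance(cohort["covariates"])
        assert (res["p"].dropna() > 0.001).all()
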