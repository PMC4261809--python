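"""Synthetic cohort generator: schedules, compositions, replicates, the
paired fine-resolution subset and qPCR emulation."""

import numpy as np
import pandas as pd
import pytest

from spikescan.simulate import (
    SPIKE_SPECIES,
    SPIKE_TAXON,
    CohortSpec,
    CompositionSpec,
    SimulationError,
    generate_cohort,
    generate_counts,
    generate_covariates,
    generate_fine_platform_subset,
    generate_qpcr,
    generate_replicates,
    null_composition,
    paired_calibration_frame,
    simulate_study,
    spike_fraction,
)


class TestCohort:
    def test_default_group_sizes(self):
        metadata, covariates = generate_cohort(CohortSpec(rng_seed=1))
        by_group = metadata.groupby("group")["subject_id"].nunique()
        assert by_group["case"] == 29
        assert by_group["control"] == 47
        assert len(covariates) == 76

    def test_minimal_cohort_two_rows(self):
        spec = CohortSpec(
            n_cases=1, n_controls=1, first_sample_age_mean=150, first_sample_age_sd=0,
            last_sample_age=150, rng_seed=2,
        )
        metadata, _ = generate_cohort(spec)
        assert len(metadata) == 2

    def test_non_positive_group_sizes_rejected(self):
        with pytest.raises(SimulationError):
            CohortSpec(n_cases=0)

    def test_schedules_monotone_within_range(self):
        metadata, _ = generate_cohort(CohortSpec(rng_seed=3))
        for _, sub in metadata.groupby("subject_id"):
            ages = sub["age_days"].to_numpy()
            assert (np.diff(ages) > 0).all()
            assert ages.max() <= 803

    def test_mean_gap_matches_interval_parameter(self):
        # Monte-Carlo check against the generator's own interval parameter
        spec = CohortSpec(n_cases=600, n_controls=600, rng_seed=4)
        metadata, _ = generate_cohort(spec)
        gaps = (
            metadata.sort_values(["subject_id", "age_days"])
            .groupby("subject_id")["age_days"]
            .diff()
            .dropna()
        )
        se = spec.sampling_interval_sd / np.sqrt(len(gaps))
        # rounding to integer days and the 7-day floor shift the mean by
        # well under the Monte-Carlo band at this scale
        assert abs(gaps.mean() - spec.sampling_interval_mean) < 3 * se + 0.1

    def test_seroconversion_only_for_cases_and_after_first_sample(self):
        metadata, covariates = generate_cohort(CohortSpec(rng_seed=5))
        cases = covariates[covariates["group"] == "case"]
        ctrls = covariates[covariates["group"] == "control"]
        assert cases["seroconversion_age_days"].notna().all()
        assert ctrls["seroconversion_age_days"].isna().all()
        first = metadata.groupby("subject_id")["age_days"].min()
        assert (cases.set_index("subject_id")["seroconversion_age_days"] > first[cases["subject_id"]].values).all()

    def test_determinism(self):
        a, ca = generate_cohort(CohortSpec(rng_seed=7))
        b, cb = generate_cohort(CohortSpec(rng_seed=7))
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(ca, cb)

    def test_covariate_imbalance_option(self):
        subjects = [f"s{i}" for i in range(400)]
        groups = {s: ("case" if i < 200 else "control") for i, s in enumerate(subjects)}
        cov = generate_covariates(subjects, groups, seed=8, imbalance={"delivery_mode": 0.5})
        rate = cov.groupby("group")["delivery_mode"].apply(lambda s: (s == "csection").mean())
        assert rate["case"] > rate["control"] + 0.2


class TestCounts:
    def test_single_mass_taxon_zero_overdispersion(self):
        taxa = {SPIKE_TAXON: 0.0, "p__X;g__Y;s__Z": 1.0}
        comp = CompositionSpec(
            taxa=taxa, overdispersion=0.0, spike_base=0.0, spike_case_level=0.0,
            spike_control_level=0.0, spike_case_plateau=0.0, spike_control_plateau=0.0,
            subject_effect_sd=0.0, spike_subject_sd=0.0,
        )
        meta = pd.DataFrame(
            {
                "sample_id": ["a", "b"], "subject_id": ["s1", "s2"], "age_days": [100, 500],
                "group": ["case", "control"], "platform": ["hiseq"] * 2, "replicate_group": ["", ""],
            }
        )
        table = generate_counts(meta, comp, seed=1)
        assert (table.counts.loc["p__X;g__Y;s__Z"] == table.sample_totals()).all()

    def test_case_mean_spike_fraction_at_peak(self):
        # 500 case subjects sampled exactly at the peak age: the generator's
        # expectation there is the pinned case level, 0.173
        comp = CompositionSpec()
        meta = pd.DataFrame(
            {
                "sample_id": [f"x{i}" for i in range(500)],
                "subject_id": [f"x{i}" for i in range(500)],
                "age_days": [int(comp.spike_peak_age)] * 500,
                "group": ["case"] * 500,
                "platform": ["hiseq"] * 500,
                "replicate_group": [""] * 500,
            }
        )
        table = generate_counts(meta, comp, seed=9)
        frac = (table.counts.loc[SPIKE_TAXON] / table.sample_totals()).to_numpy()
        se = frac.std(ddof=1) / np.sqrt(len(frac))
        assert abs(frac.mean() - comp.spike_case_level) < 3 * se + 0.01

    def test_control_curve_pinned_at_peak(self):
        comp = CompositionSpec()
        assert spike_fraction(comp.spike_peak_age, "control", comp) == pytest.approx(
            comp.spike_control_level
        )
        assert spike_fraction(comp.spike_peak_age, "case", comp) == pytest.approx(
            comp.spike_case_level
        )

    def test_fixed_seed_bit_identical(self, cohort):
        t1 = generate_counts(cohort["metadata"], cohort["comp"], seed=33)
        t2 = generate_counts(cohort["metadata"], cohort["comp"], seed=33)
        pd.testing.assert_frame_equal(t1.counts, t2.counts)

    def test_unknown_shallow_sample_rejected(self, cohort):
        with pytest.raises(SimulationError, match="unknown sample ids"):
            generate_counts(cohort["metadata"], cohort["comp"], seed=1, shallow_sample_ids=["nope"])

    def test_empty_metadata_rejected(self, cohort):
        with pytest.raises(SimulationError, match="empty"):
            generate_counts(cohort["metadata"].iloc[:0], cohort["comp"])

    def test_injected_shallow_samples_fail_depth_filter(self, cohort):
        from spikescan.tables import filter_low_depth

        shallow = list(cohort["metadata"]["sample_id"].iloc[:3])
        table = generate_counts(cohort["metadata"], cohort["comp"], seed=12, shallow_sample_ids=shallow)
        _, excluded = filter_low_depth(table, 10_000)
        assert sorted(excluded) == sorted(shallow)


class TestReplicates:
    def test_k_below_two_rejected(self, tiny_table):
        with pytest.raises(SimulationError):
            generate_replicates(tiny_table, CompositionSpec(), k=1)

    def test_k2_on_10_samples_gives_20_columns(self, cohort):
        ids = cohort["table"].sample_ids[:10]
        reps, meta = generate_replicates(cohort["table"], CompositionSpec(), k=2, sample_ids=ids, seed=1)
        assert len(reps.sample_ids) == 20
        assert meta["replicate_group"].nunique() == 10

    def test_zero_noise_is_pure_multinomial_resample(self, tiny_table):
        comp = CompositionSpec(replicate_noise_scale=0.0)
        reps, _ = generate_replicates(tiny_table, comp, k=2, sample_ids=["s1"], seed=3)
        # totals preserved; expected composition equals the source sample's
        assert (reps.sample_totals() == 10_000).all()
        src = tiny_table.counts["s1"] / 10_000
        got = reps.counts.mean(axis=1) / 10_000
        assert np.allclose(src, got, atol=0.02)

    def test_cv_larger_at_low_abundance(self):
        # ~200 replicate groups: within-group CV at ~0.1% abundance exceeds
        # the CV at ~10% abundance
        rng = np.random.default_rng(11)
        base = np.array([0.899, 0.1, 0.001])
        taxa = pd.Index(["hi", "mid", "lo"], name="taxon_id")
        cols = {f"g{i}": rng.multinomial(50_000, base) for i in range(200)}
        from spikescan.tables import TaxonCountTable

        table = TaxonCountTable(
            pd.DataFrame(cols, index=taxa), pd.Series(["p__A", "p__B", "p__C"], index=taxa)
        )
        reps, _ = generate_replicates(table, CompositionSpec(), k=3, seed=12)
        cvs = {}
        for taxon in ["mid", "lo"]:
            vals = []
            for g in cols:
                block = reps.counts.loc[taxon, [f"{g}_rep{r}" for r in (1, 2, 3)]].to_numpy()
                frac = block / 50_000
                if frac.mean() > 0:
                    vals.append(frac.std(ddof=1) / frac.mean())
            cvs[taxon] = np.mean(vals)
        assert cvs["lo"] > cvs["mid"]


class TestFinePlatform:
    def test_full_dorei_fraction_leaves_second_species_empty(self, cohort):
        comp = CompositionSpec(dorei_fraction_of_group=1.0)
        fine = generate_fine_platform_subset(cohort["table"], comp, n_samples=50, seed=1)
        assert fine.counts.loc[SPIKE_SPECIES[1]].sum() == 0

    def test_pooled_share_recovers_dorei_fraction(self, cohort):
        comp = CompositionSpec()
        fine = generate_fine_platform_subset(cohort["table"], comp, n_samples=500, seed=2)
        s1 = fine.counts.loc[SPIKE_SPECIES[0]].sum()
        s2 = fine.counts.loc[SPIKE_SPECIES[1]].sum()
        total = s1 + s2
        se = np.sqrt(0.75 * 0.25 / total)
        assert abs(s1 / total - 0.75) < 3 * se + 1e-3

    def test_zero_group_sample_gives_zero_species(self, tiny_table):
        table = tiny_table.copy()
        table.counts.loc["tA", "s2"] = 0
        table.lineage["tA"] = SPIKE_TAXON
        table.counts.index = pd.Index([SPIKE_TAXON, "tB", "tC"], name="taxon_id")
        table.lineage.index = table.counts.index
        table.lineage[SPIKE_TAXON] = SPIKE_TAXON
        fine = generate_fine_platform_subset(table, CompositionSpec(), n_samples=2, seed=3)
        assert fine.counts.loc[SPIKE_SPECIES[0], "s2"] == 0
        assert fine.counts.loc[SPIKE_SPECIES[1], "s2"] == 0

    def test_oversized_subset_rejected(self, tiny_table):
        table = tiny_table.copy()
        table.counts.index = pd.Index([SPIKE_TAXON, "tB", "tC"], name="taxon_id")
        table.lineage = pd.Series(table.counts.index, index=table.counts.index)
        with pytest.raises(SimulationError, match="exceeds"):
            generate_fine_platform_subset(table, CompositionSpec(), n_samples=3000)

    def test_paired_frame_schema(self, cohort):
        fine = generate_fine_platform_subset(cohort["table"], CompositionSpec(), n_samples=93, seed=4)
        pairs = paired_calibration_frame(cohort["table"], fine)
        assert len(pairs) == 93
        assert {"group_fraction", "species1_fraction", "species2_fraction"} <= set(pairs.columns)


class TestQpcr:
    def test_zero_noise_exactly_proportional(self, tiny_table):
        table = tiny_table.copy()
        table.counts.index = pd.Index([SPIKE_TAXON, "tB", "tC"], name="taxon_id")
        table.lineage = pd.Series(table.counts.index, index=table.counts.index)
        q = generate_qpcr(table, noise=0.0, triplicate_noise=0.0, total_load=1e6, seed=1)
        rel = table.counts.loc[SPIKE_TAXON] / table.sample_totals()
        assert np.allclose(q["rep1"], rel.values * 1e6)

    def test_negative_noise_rejected(self, tiny_table):
        with pytest.raises(SimulationError):
            generate_qpcr(tiny_table, noise=-0.1)

    def test_empty_taxon_selection_rejected(self, tiny_table):
        with pytest.raises(SimulationError, match="empty taxon"):
            generate_qpcr(tiny_table, taxa=[])

    def test_copies_strictly_positive(self, cohort):
        q = generate_qpcr(cohort["table"], sample_ids=cohort["table"].sample_ids[:20], seed=2)
        assert (q[["rep1", "rep2", "rep3"]].to_numpy() > 0).all()


class TestStudyBundle:
    def test_bundle_determinism_and_null_mode(self):
        spec = CohortSpec(n_cases=4, n_controls=5, rng_seed=21)
        b1 = simulate_study(spec, n_fine_samples=10, n_qpcr_samples=5, n_replicate_samples=5)
        b2 = simulate_study(spec, n_fine_samples=10, n_qpcr_samples=5, n_replicate_samples=5)
        pd.testing.assert_frame_equal(b1["counts"].counts, b2["counts"].counts)
        pd.testing.assert_frame_equal(b1["qpcr"], b2["qpcr"])
        null = null_composition()
        assert null.spike_case_level == null.spike_control_level
        assert null.spike_case_plateau == null.spike_control_plateau
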