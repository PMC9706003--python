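"""Genotype arithmetic and the virtual-cohort generator."""

import math

import numpy as np
import pytest

import tacropk as tp
from tacropk.cohort import SNP_TABLE, hwe_exact_test


class TestAlleleFrequency:
    def test_cyp3a5_star1_from_cohort_counts(self):
        assert tp.allele_frequency(18, 58, 63) == pytest.approx(0.338, abs=5e-4)

    def test_myh9_t_from_cohort_counts(self):
        assert tp.allele_frequency(52, 64, 23) == pytest.approx(0.604, abs=5e-4)

    def test_monomorphic_is_unity(self):
        assert tp.allele_frequency(25, 0, 0) == 1.0

    def test_all_twelve_snps_match_reported_to_printed_precision(self):
        for snp in SNP_TABLE:
            assert snp.freq == pytest.approx(snp.reported_freq, abs=1e-3), (
                snp.column
            )

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            tp.allele_frequency(0, 0, 0)


class TestHardyWeinberg:
    def test_exact_proportions_give_zero_statistic(self):
        # p=0.5, n=100: 25/50/25 is exactly at HWE expectation
        chi2, p = tp.hwe_chi_square(25, 50, 25)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_cyp3a5_counts_hand_computation(self):
        # expected counts 15.89 / 62.22 / 60.90 at p=0.338
        chi2, p = tp.hwe_chi_square(18, 58, 63)
        assert chi2 == pytest.approx(0.64, abs=0.02)
        assert p == pytest.approx(0.42, abs=0.01)

    def test_maximal_disequilibrium_rejected(self):
        chi2, p = tp.hwe_chi_square(50, 0, 50)
        assert chi2 > 50
        assert p < 1e-10

    def test_monomorphic_convention(self):
        assert tp.hwe_chi_square(40, 0, 0) == (0.0, 1.0)

    def test_exact_test_against_enumeration_oracle(self):
        """Small-sample exact SNP-HWE p-value versus brute-force enumeration
        of all heterozygote counts conditional on the allele counts."""
        cases = [(2, 4, 4), (1, 2, 7), (3, 0, 7), (0, 6, 4)]
        for n_aa, n_ab, n_bb in cases:
            n = n_aa + n_ab + n_bb
            rare = 2 * n_aa + n_ab
            # enumerate P(het = h | allele counts) ~ multinomial conditioning
            probs = {}
            for h in range(rare % 2, rare + 1, 2):
                aa = (rare - h) // 2
                bb = n - aa - h
                if bb < 0:
                    continue
                logp = (
                    math.lgamma(n + 1)
                    - math.lgamma(aa + 1) - math.lgamma(h + 1)
                    - math.lgamma(bb + 1) + h * math.log(2)
                )
                probs[h] = math.exp(logp)
            z = sum(probs.values())
            obs = probs[n_ab] / z
            oracle = sum(v / z for v in probs.values()
                         if v / z <= obs * (1 + 1e-12))
            assert hwe_exact_test(n_aa, n_ab, n_bb) == pytest.approx(
                oracle, rel=1e-9
            ), (n_aa, n_ab, n_bb)


class TestSampleGenotypes:
    def test_fixed_allele_gives_all_major_homozygotes(self):
        snp = SNP_TABLE[0]
        fixed = snp.__class__(snp.column, snp.genotypes, (100, 0, 0),
                              snp.alleles, 1.0)
        g = tp.sample_genotypes(50, (fixed,), rng=0)
        assert (g[snp.column] == snp.genotypes[0]).all()

    def test_large_sample_frequency_within_binomial_bound(self):
        snp = next(s for s in SNP_TABLE if s.column == "CYP3A5_rs776746")
        n = 10_000
        g = tp.sample_genotypes(n, (snp,), rng=123)
        calls = g[snp.column]
        freq = (2 * (calls == "*1/*1").sum() + (calls == "*1/*3").sum()) / (2 * n)
        p = snp.freq
        sd = math.sqrt(p * (1 - p) / (2 * n))
        assert abs(freq - p) < 3 * sd

    def test_deterministic_per_seed(self):
        a = tp.sample_genotypes(30, SNP_TABLE, rng=9)
        b = tp.sample_genotypes(30, SNP_TABLE, rng=9)
        assert a.equals(b)

    def test_cohort_scale_draws_usually_pass_hwe(self):
        rejections = 0
        n_tests = 0
        for seed in range(10):
            g = tp.sample_genotypes(139, SNP_TABLE, rng=seed)
            for snp in SNP_TABLE:
                counts = [int((g[snp.column] == lv).sum())
                          for lv in snp.genotypes]
                _, p = tp.hwe_chi_square(*counts)
                n_tests += 1
                rejections += p < 0.05
        assert rejections / n_tests < 0.12  # nominal 5%


class TestGenerateCohort:
    def test_default_design_matches_study_shape(self):
        counts, peaks = [], []
        for seed in range(5):
            table, _ = tp.generate_cohort(tp.CohortDesign(seed=seed))
            assert table.n_subjects == 139
            obs = table.observations()
            counts.append(len(obs))
            peaks.append((obs["SAMPLE"] == "peak").sum())
        assert 380 < np.mean(counts) < 480   # ~432 planned samples
        assert 20 < np.mean(peaks) < 50      # ~35 peaks

    def test_no_wuzhi_when_probability_zero(self):
        design = tp.CohortDesign(n_subjects=30, comb_wz_p=0.0, seed=5)
        table, _ = tp.generate_cohort(design)
        assert (table.covariates()["COMBWZ"] == 0).all()

    def test_median_age_near_study_median_across_seeds(self):
        medians = []
        for seed in range(20):
            table, _ = tp.generate_cohort(
                tp.CohortDesign(n_subjects=139, seed=seed)
            )
            medians.append(table.covariates()["AGE"].median())
        assert 4.5 <= np.median(medians) <= 6.5
        ages = table.covariates()["AGE"]
        assert ages.min() >= 1.1 and ages.max() <= 15.6

    def test_doses_stay_inside_label_range(self):
        table, _ = tp.generate_cohort(tp.CohortDesign(seed=2))
        amts = table.doses()["AMT"]
        assert amts.min() >= 500 and amts.max() <= 3000

    def test_infeasible_design_rejected(self):
        with pytest.raises(ValueError):
            tp.CohortDesign(visit_days=())
        with pytest.raises(ValueError):
            tp.CohortDesign(dose_range=(100, 3000))

    def test_distinct_seeds_give_distinct_cohorts(self):
        t1, _ = tp.generate_cohort(tp.CohortDesign(n_subjects=10, seed=1))
        t2, _ = tp.generate_cohort(tp.CohortDesign(n_subjects=10, seed=2))
        assert not t1.df.equals(t2.df)


class TestSimulateObservations:
    def test_noise_free_simulation_equals_deterministic_profile(self,
                                                                truth_spec):
        import pandas as pd

        design = tp.CohortDesign(n_subjects=8, seed=33)
        table, _ = tp.generate_cohort(design, truth=truth_spec)
        clean = truth_spec.with_updates(sigma=1e-12)
        zero = pd.DataFrame({"ID": table.subject_ids,
                             "eta_cl": 0.0, "eta_v": 0.0})
        sim = tp.simulate_observations(table, clean, rng=0, etas=zero)
        df = sim.df
        for sid in table.subject_ids[:3]:
            doses = df[(df["ID"] == sid) & (df["EVID"] == 1)]
            obs = df[(df["ID"] == sid) & (df["EVID"] == 0)]
            p = tp.individual_params(truth_spec,
                                     obs.iloc[0][["AGE"]].to_dict()
                                     | {c: obs.iloc[0][c] for c in
                                        ("CTLA4_GA", "CTLA4_AA",
                                         "CYP3A5_33", "COMBWZ")})
            oracle = tp.conc_profile(doses["AMT"].to_numpy(),
                                     doses["TIME"].to_numpy(),
                                     obs["TIME"].to_numpy(), p)
            np.testing.assert_allclose(obs["DV"].to_numpy(), oracle,
                                       rtol=1e-6)

    def test_doubling_doses_doubles_noise_free_concentrations(self,
                                                              truth_spec):
        import pandas as pd

        design = tp.CohortDesign(n_subjects=6, seed=44)
        table, _ = tp.generate_cohort(design, truth=truth_spec)
        clean = truth_spec.with_updates(sigma=1e-12)
        zero = pd.DataFrame({"ID": table.subject_ids,
                             "eta_cl": 0.0, "eta_v": 0.0})
        sim1 = tp.simulate_observations(table, clean, rng=0, etas=zero)
        doubled = table.df.copy()
        doubled.loc[doubled["EVID"] == 1, "AMT"] *= 2
        sim2 = tp.simulate_observations(tp.EventTable(doubled), clean,
                                        rng=0, etas=zero)
        np.testing.assert_allclose(
            sim2.observations()["DV"].to_numpy(),
            2 * sim1.observations()["DV"].to_numpy(), rtol=1e-9,
        )

    def test_titrated_troughs_concentrate_in_target_window(self, study_sim):
        sim, _ = study_sim
        tro = sim.df[(sim.df["EVID"] == 0) & (sim.df["SAMPLE"] == "trough")]
        med = tro["DV"].median()
        assert 3.0 < med < 12.0  # 5-10 ug/L policy, plus noise and refractory subjects

    def test_determinism_per_seed(self, truth_spec):
        design = tp.CohortDesign(n_subjects=10, seed=3)
        t1, e1 = tp.generate_cohort(design)
        t2, e2 = tp.generate_cohort(design)
        assert t1.df.equals(t2.df) and e1.equals(e2)
        s1 = tp.simulate_observations(t1, truth_spec, rng=5, etas=e1)
        s2 = tp.simulate_observations(t2, truth_spec, rng=5, etas=e2)
        assert s1.df.equals(s2.df)

    def test_below_lloq_flagged_not_censored(self, truth_spec):
        design = tp.CohortDesign(n_subjects=50, seed=8)
        table, etas = tp.generate_cohort(design)
        sim = tp.simulate_observations(table, truth_spec, rng=9, etas=etas)
        obs = sim.df[sim.df["EVID"] == 0]
        assert (obs["DV"] > 0).all()
        low = obs[obs["DV"] < 0.5]
        if len(low):
            assert (low["BLQ"] == 1).all()
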