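import math

import numpy as np
import pytest
from scipy import stats as sps

from evquant.calibration import fit_size_calibration
from evquant.fractions import elution_window, normalize_profile, peak_fraction
from evquant.gating import percent_positive, quadrant, threshold_from_control
from evquant.simulate import (
    BSA_POPULATION,
    EV_POPULATION,
    NOISE_POPULATION,
    AntibodyModel,
    CohortConfig,
    PopulationSpec,
    SampleConfig,
    gen_bead_events,
    gen_cohort,
    gen_dilution_series,
    gen_fraction_profile,
    gen_sample_events,
)


class TestGenSampleEvents:
    def test_determinism(self):
        cfg = SampleConfig(seed=42, antibody=AntibodyModel())
        assert gen_sample_events(cfg) == gen_sample_events(cfg)

    def test_distinct_seeds_distinct_tables(self):
        a = gen_sample_events(SampleConfig(seed=1))
        b = gen_sample_events(SampleConfig(seed=2))
        assert a != b

    def test_noise_only_sits_at_noise_floor(self):
        spec = NOISE_POPULATION
        sample = gen_sample_events(SampleConfig(populations=(spec,), seed=11))
        control = gen_sample_events(SampleConfig(populations=(spec,), seed=12))
        thr = threshold_from_control(control, "fl1", rule="percentile")
        # same-distribution draws: ~0.1% expected above the 99.9th pctile
        assert percent_positive(sample, thr) <= 1.0

    def test_display_prob_recovered_by_quadrant(self, noise_control):
        ab = AntibodyModel(amount_ug=1000.0, display_prob=0.5)
        sample = gen_sample_events(
            SampleConfig(populations=(EV_POPULATION,), antibody=ab, seed=7)
        )
        thr1 = threshold_from_control(noise_control, "fl1")
        thr4 = threshold_from_control(noise_control, "fl4")
        q = quadrant(sample, thr1, thr4)
        sd = 100 * math.sqrt(0.25 / q.n_fl1_pos)
        assert abs(q.display_pct - 50.0) < 3 * sd

    def test_poisson_population_size(self):
        n = len(gen_sample_events(SampleConfig(seed=3)))
        expect = EV_POPULATION.n_events_expected
        assert abs(n - expect) < 5 * math.sqrt(expect)

    def test_detergent_moves_ev_fl1_to_noise(self, noise_control):
        thr = threshold_from_control(noise_control, "fl1")
        plain = gen_sample_events(SampleConfig(seed=21))
        treated = gen_sample_events(SampleConfig(seed=21, detergent=True))
        assert percent_positive(plain, thr) > 50
        assert percent_positive(treated, thr) < 5

    def test_detergent_statistically_matches_pure_noise(self):
        # big reference draw pins down the per-event positive probability
        ref = gen_sample_events(SampleConfig(
            populations=(PopulationSpec(
                100_000, NOISE_POPULATION.fl1_log10_mean,
                NOISE_POPULATION.fl1_log10_sd, 2.9, 0.2, "noise"),),
            seed=500))
        control = gen_sample_events(
            SampleConfig(populations=(NOISE_POPULATION,), seed=501))
        thr = threshold_from_control(control, "fl1")
        p_ref = percent_positive(ref, thr) / 100.0
        treated = gen_sample_events(SampleConfig(seed=502, detergent=True))
        k = round(percent_positive(treated, thr) / 100.0 * len(treated))
        test = sps.binomtest(int(k), len(treated), p_ref, alternative="two-sided")
        assert test.pvalue > 0.01

    def test_detergent_leaves_protein_particles_bright(self, noise_control):
        thr = threshold_from_control(noise_control, "fl1")
        cfg = SampleConfig(populations=(BSA_POPULATION,), seed=31, detergent=True)
        assert percent_positive(gen_sample_events(cfg), thr) > 50

    def test_trypan_quenches_fl1_everywhere(self, noise_control):
        thr = threshold_from_control(noise_control, "fl1")
        cfg = SampleConfig(seed=41, bsa_present=True, trypan_blue=True)
        assert percent_positive(gen_sample_events(cfg), thr) < 5

    def test_trypan_brightens_protein_fl4(self, noise_control):
        thr4 = threshold_from_control(noise_control, "fl4")
        cfg = SampleConfig(populations=(BSA_POPULATION,), seed=42, trypan_blue=True)
        assert percent_positive(gen_sample_events(cfg), thr4) > 50

    def test_bsa_flag_adds_population(self):
        base = gen_sample_events(SampleConfig(seed=5))
        with_bsa = gen_sample_events(SampleConfig(seed=5, bsa_present=True))
        assert len(with_bsa) > len(base) * 1.5

    def test_dose_response_monotone_log_linear(self, noise_control):
        thr1 = threshold_from_control(noise_control, "fl1")
        thr4 = threshold_from_control(noise_control, "fl4")
        amounts = [0.03, 0.1, 0.3, 1.0]
        pcts = []
        for i, amount in enumerate(amounts):
            ab = AntibodyModel(amount_ug=amount, display_prob=1.0)
            big_ev = PopulationSpec(
                20_000, EV_POPULATION.fl1_log10_mean, EV_POPULATION.fl1_log10_sd,
                3.0, 0.2, "ev")
            s = gen_sample_events(
                SampleConfig(populations=(big_ev,), antibody=ab, seed=600 + i))
            pcts.append(quadrant(s, thr1, thr4).display_pct)
        assert pcts == sorted(pcts)
        # mid-range approximate linearity in log amount: interior point close
        # to the chord between its neighbours
        x = np.log10(amounts)
        interp = pcts[1] + (pcts[2] - pcts[1]) * (x[2] - x[1]) / (x[2] - x[1])
        assert abs(pcts[2] - interp) < 10

    def test_invalid_population_kind(self):
        with pytest.raises(ValueError):
            PopulationSpec(10, 1, 0.1, 3, 0.1, "mystery")

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            PopulationSpec(10, 1, -0.1, 3, 0.1, "noise")


class TestGenCohort:
    def test_zero_sd_collapses_to_means(self):
        cfg = CohortConfig(sd_pos=0, sd_neg=0, replicate_sd=0, seed=1)
        df = gen_cohort(cfg)
        preg = df.loc[df.group == "pregnant", "display_pct"]
        ctrl = df.loc[df.group == "control", "display_pct"]
        assert (preg == cfg.mean_pos).all()
        assert (ctrl == cfg.mean_neg).all()

    def test_law_of_large_numbers(self):
        cfg = CohortConfig(n_per_group=10_000, replicates=1, seed=2)
        df = gen_cohort(cfg)
        means = df.groupby("group")["display_pct"].mean()
        assert abs(means["pregnant"] - 21.5) < 0.5
        assert abs(means["control"] - 33.0) < 0.5

    def test_seed_reproducibility(self):
        cfg = CohortConfig(seed=9)
        assert gen_cohort(cfg).equals(gen_cohort(cfg))

    def test_values_bounded(self):
        cfg = CohortConfig(mean_pos=2.0, sd_pos=5.0, n_per_group=200, seed=3)
        vals = gen_cohort(cfg)["display_pct"]
        assert (vals >= 0).all() and (vals <= 100).all()

    def test_isotype_group_optional(self):
        df = gen_cohort(CohortConfig(include_isotype=True, seed=4))
        assert set(df.group) == {"pregnant", "control", "isotype"}

    def test_binormal_auc_matches_closed_form(self):
        # closed-form binormal AUC for the default group summaries
        from evquant.stats import auc, roc_points

        expected = sps.norm.cdf(abs(33.0 - 21.5) / math.sqrt(3.0**2 + 5.9**2))
        assert abs(expected - 0.959) < 1e-3
        cfg = CohortConfig(n_per_group=5000, replicates=1, replicate_sd=0, seed=5)
        df = gen_cohort(cfg)
        pos = df.loc[df.group == "pregnant", "display_pct"].to_numpy()
        neg = df.loc[df.group == "control", "display_pct"].to_numpy()
        empirical = auc(roc_points(pos, neg, "positive_if_below"))
        assert abs(empirical - expected) < 0.01

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            CohortConfig(sd_pos=-1)
        with pytest.raises(ValueError):
            CohortConfig(n_per_group=0)


class TestGenBeadEvents:
    def test_zero_cv_gives_exact_medians(self):
        table, labels = gen_bead_events([30, 100, 500], events_per_bead=50,
                                        fsc_cv=0.0, law=(2.0, 2.0), seed=1)
        fsc = table.channel("fsc_h")
        for lab, size in enumerate([30, 100, 500]):
            cluster = fsc[labels == lab]
            assert np.allclose(cluster, 2.0 * size**2)

    def test_calibration_recovers_exponent(self):
        table, labels = gen_bead_events([30, 100, 500], events_per_bead=2000,
                                        fsc_cv=0.05, law=(1.0, 2.0), seed=2)
        fsc = table.channel("fsc_h")
        beads = [(s, float(np.median(fsc[labels == i])))
                 for i, s in enumerate([30, 100, 500])]
        cal = fit_size_calibration(beads, basis="median")
        assert abs(cal.slope - 2.0) < 0.05

    def test_single_size_single_cluster(self):
        table, labels = gen_bead_events([100], events_per_bead=10, seed=3)
        assert set(labels.tolist()) == {0}
        assert len(table) == 10

    def test_duplicate_sizes_rejected(self):
        with pytest.raises(ValueError):
            gen_bead_events([100, 100])

    def test_determinism(self):
        a, _ = gen_bead_events([30, 100], seed=4)
        b, _ = gen_bead_events([30, 100], seed=4)
        assert a == b


class TestGenDilutionSeries:
    FACTORS = [1.0, 0.5, 0.2, 0.1, 0.05, 0.025, 0.0125]

    def test_no_swarm_limit_proportional(self):
        df = gen_dilution_series(1e6, self.FACTORS, seed=1)
        expected = 1e6 * np.array(self.FACTORS)
        # Poisson error: 5 sigma band
        assert np.all(np.abs(df.detected_count - expected) < 5 * np.sqrt(expected))

    def test_swarm_undercounts_at_high_concentration(self):
        df = gen_dilution_series(1e6, [1.0, 0.1], saturation_count=1e5, seed=2)
        detected = dict(zip(df.dilution_factor, df.detected_count))
        assert detected[1.0] < 10 * detected[0.1]

    def test_expected_matches_model(self):
        df = gen_dilution_series(1e6, [0.5], saturation_count=1e5, seed=3)
        true = 5e5
        assert math.isclose(df.expected_count[0], true * math.exp(-true / 1e5))

    def test_seed_determinism(self):
        a = gen_dilution_series(1e4, self.FACTORS, seed=9)
        b = gen_dilution_series(1e4, self.FACTORS, seed=9)
        assert a.equals(b)

    def test_invalid_factor(self):
        with pytest.raises(ValueError):
            gen_dilution_series(1e4, [0.0, 0.5])
        with pytest.raises(ValueError):
            gen_dilution_series(1e4, [1.5])


class TestGenFractionProfile:
    def test_zero_amplitude_flat(self):
        p = gen_fraction_profile(5, 1.5, amplitude=0.0, baseline=2.0)
        assert np.allclose(p.as_array(), 2.0)

    def test_peak_location(self):
        p = gen_fraction_profile(5, 1.5, amplitude=3.0)
        assert peak_fraction(p) == 5

    def test_gaussian_window_closed_form(self):
        # 10%-of-max support half-width = sigma * sqrt(2 ln 10) ~ 4.29
        p = gen_fraction_profile(9.5, 2.0, amplitude=1.0, baseline=0.0)
        w = elution_window(normalize_profile(p), rel_threshold=0.1)
        half = 2.0 * math.sqrt(2 * math.log(10))
        lo = math.ceil(9.5 - half)   # first integer fraction inside support
        hi = math.floor(9.5 + half)
        assert (w.start, w.stop) == (lo, hi)
        # continuous support [5.21, 13.79] -> integer fractions 6..13,
        # symmetric about the 9.5 peak between fractions 9 and 10
        assert w.n_fractions == 8
        assert w.start + w.stop == 19

    def test_peak_out_of_range(self):
        with pytest.raises(ValueError):
            gen_fraction_profile(0, 1.0)
        with pytest.raises(ValueError):
            gen_fraction_profile(21, 1.0)
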