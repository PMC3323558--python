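"""Synthetic-study generator: pedigrees, genotypes, lifespans, and
ascertainment-design evaluation."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import stats as sps

from apmscan.phenotype import SelectionRule
from apmscan.simulate import (
    SimConfig,
    evaluate_selection_design,
    gompertz_mean,
    gompertz_quantile,
    make_scan_fixture,
    simulate_genotypes,
    simulate_lifespans,
    simulate_pedigree,
)

SMALL = SimConfig(
    n_founder_couples=4, n_generations=3, mean_offspring=3.0,
    causal_allele_freq=0.1, chrom_lengths_cm=(60.0,), causal_chrom="1",
    causal_position_cm=30.0,
)


class TestSimulatePedigree:
    def test_nuclear_family(self):
        cfg = SimConfig(n_founder_couples=1, n_generations=2,
                        mean_offspring=3.0, offspring_dispersion=0)
        ped = simulate_pedigree(cfg, 0)
        assert len(ped) == 5
        assert len(ped.founders) == 2

    def test_four_generations_validate(self):
        cfg = SimConfig(n_founder_couples=2, n_generations=4, mean_offspring=2.5)
        ped = simulate_pedigree(cfg, 1)
        # construction invariant: validate_pedigree passes (constructor ran)
        assert len(ped.founders) >= 4
        assert all(ped.inbreeding(i) == 0.0 for i in ped.ids)

    def test_realized_sibship_mean(self):
        """Mean offspring count per reproducing couple matches the
        configured mean within 3 SE over many kindreds."""
        cfg = SimConfig(n_founder_couples=100, n_generations=2, mean_offspring=6.0)
        ped = simulate_pedigree(cfg, 2)
        sibs = len(ped) - 200  # children of the 100 founder couples
        se = math.sqrt(6.0 / 100)
        assert abs(sibs / 100 - 6.0) < 3 * se

    def test_zero_offspring_mean_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(mean_offspring=0.0)


class TestSimulateGenotypes:
    def test_no_missingness_gives_complete_panel(self):
        cfg = dataclasses.replace(SMALL, missingness_rate=0.0)
        ped = simulate_pedigree(cfg, 3)
        panel, gmap, freqs, copies = simulate_genotypes(ped, cfg, 3)
        assert (panel.call_rate() == 1.0).all()

    def test_missingness_applied_to_markers_not_truth(self):
        cfg = dataclasses.replace(SMALL, missingness_rate=0.3)
        ped = simulate_pedigree(cfg, 4)
        panel, _, _, copies = simulate_genotypes(ped, cfg, 4)
        assert (panel.call_rate() < 1.0).any()
        assert set(copies) == set(ped.ids)  # every individual has truth

    def test_founder_carrier_fraction_hardy_weinberg(self):
        """Carrier fraction among founders ~ 1 - (1-p)^2 within 3 SE."""
        cfg = SimConfig(n_founder_couples=600, n_generations=2,
                        mean_offspring=1.0, causal_allele_freq=0.05)
        ped = simulate_pedigree(cfg, 5)
        _, _, _, copies = simulate_genotypes(ped, cfg, 5)
        founders = ped.founders
        frac = np.mean([copies[f] >= 1 for f in founders])
        p_expect = 1 - 0.95**2
        se = math.sqrt(p_expect * (1 - p_expect) / len(founders))
        assert abs(frac - p_expect) < 3 * se

    def test_allele_counts_within_configured_range(self):
        cfg = dataclasses.replace(SMALL, allele_count_range=(3, 6))
        ped = simulate_pedigree(cfg, 6)
        panel, gmap, freqs, _ = simulate_genotypes(ped, cfg, 6)
        for m in panel.markers:
            assert 3 <= freqs.alleles(m).size <= 6

    def test_mean_marker_spacing_near_target(self):
        cfg = dataclasses.replace(SMALL, chrom_lengths_cm=(150.0,))
        ped = simulate_pedigree(cfg, 7)
        _, gmap, _, _ = simulate_genotypes(ped, cfg, 7)
        pos = gmap.positions("1")
        assert np.diff(pos).mean() == pytest.approx(3.4, abs=0.2)


class TestSimulateLifespans:
    def _ped(self, n=5000):
        cfg = SimConfig(n_founder_couples=n // 2, n_generations=2,
                        mean_offspring=0.1)
        return simulate_pedigree(cfg, 8)

    def test_hr_one_is_null(self):
        """With HR=1 carrier and non-carrier lifespans are identically
        distributed (two-sample KS)."""
        cfg = dataclasses.replace(SMALL, hazard_ratio=1.0)
        ped = self._ped()
        # carrier labels independent of sex (sex shifts the baseline hazard)
        ids = [i for i in ped.ids if ped[i].sex == "female"]
        rng = np.random.default_rng(99)
        copies = {i: int(rng.random() < 0.5) for i in ids}
        ages = simulate_lifespans(ped, copies, cfg, 9)
        car = [ages[i] for i in ids if copies[i] >= 1]
        non = [ages[i] for i in ids if copies[i] == 0]
        assert sps.ks_2samp(car, non).pvalue > 0.01

    def test_hr_half_shifts_median_by_closed_form(self):
        """Carrier median age matches the Gompertz proportional-hazards
        quantile with hazard a*HR."""
        cfg = dataclasses.replace(SMALL, hazard_ratio=0.5)
        ped = self._ped()
        ids = [i for i in ped.ids if ped[i].sex == "female"]
        rng = np.random.default_rng(98)
        copies = {i: int(rng.random() < 0.5) for i in ids}
        ages = simulate_lifespans(ped, copies, cfg, 10)
        car = np.array([ages[i] for i in ids if copies[i] >= 1])
        non = np.array([ages[i] for i in ids if copies[i] == 0])
        med_car_expect = gompertz_quantile(0.5, cfg.gompertz_a * 0.5, cfg.gompertz_b)
        med_non_expect = gompertz_quantile(0.5, cfg.gompertz_a, cfg.gompertz_b)
        assert np.median(car) > np.median(non)
        assert np.median(car) == pytest.approx(med_car_expect, abs=1.5)
        assert np.median(non) == pytest.approx(med_non_expect, abs=1.5)

    def test_seeded_rerun_identical(self):
        ped = self._ped(200)
        copies = {i: 0 for i in ped.ids}
        a1 = simulate_lifespans(ped, copies, SMALL, 11)
        a2 = simulate_lifespans(ped, copies, SMALL, 11)
        assert a1 == a2

    def test_gompertz_mean_consistency(self):
        """Numerical mean matches simulated mean."""
        cfg = SMALL
        ped = self._ped()
        ages = simulate_lifespans(ped, {}, cfg, 12)
        females = [ages[i] for i in ped.ids if ped[i].sex == "female"]
        mu = gompertz_mean(cfg.gompertz_a, cfg.gompertz_b)
        assert np.mean(females) == pytest.approx(mu, abs=0.8)


class TestFixtureAndDesign:
    def test_files_round_trip(self, tmp_path):
        from apmscan.pipeline import read_study_inputs

        study = make_scan_fixture(SMALL, 13, out_dir=tmp_path)
        inputs = read_study_inputs(
            tmp_path / "study.ped",
            tmp_path / "study.map",
            tmp_path / "study.phen.tsv",
            tmp_path / "study.expected.tsv",
            freq_path=tmp_path / "study.freq.tsv",
        )
        assert set(inputs.ped.ids) == set(study.ped.ids)
        assert inputs.panel.markers == study.panel.markers
        assert np.array_equal(
            inputs.panel.geno[
                [inputs.panel._idx[i] for i in study.panel.ids]
            ],
            study.panel.geno,
        )
        for m in study.panel.markers[:3]:
            for a in study.freqs.alleles(m):
                assert inputs.freqs.frequency(m, int(a)) == pytest.approx(
                    study.freqs.frequency(m, int(a)), abs=1e-7
                )

    def test_carrier_truth_consistent_with_copies(self):
        study = make_scan_fixture(SMALL, 14)
        for iid in study.ped.ids:
            assert (iid in study.carriers) == (study.causal_copies[iid] >= 1)

    def test_carriers_live_longer_on_average(self):
        cfg = dataclasses.replace(
            SMALL, n_founder_couples=40, causal_allele_freq=0.2
        )
        study = make_scan_fixture(cfg, 15)
        ages = study.phenotypes["attained_age"]
        car = ages[ages.index.isin(study.carriers)]
        non = ages[~ages.index.isin(study.carriers)]
        assert car.mean() > non.mean()

    def test_design_evaluation_null_ppv_matches_prevalence(self):
        """With HR=1, selection is uninformative: PPV ~ carrier prevalence."""
        cfg = dataclasses.replace(
            SMALL, hazard_ratio=1.0, causal_allele_freq=0.2, n_founder_couples=8
        )
        rule = SelectionRule("el_fel_thresholds", el_min=0.0, fel_min=0.0)
        out = evaluate_selection_design(cfg, rule, n_sim=12, seed=16,
                                        use_quartiles=True)
        se = 3 * max(out["ppv_se"], 0.02)
        assert abs(out["ppv"] - out["carrier_prevalence"]) < se + 0.03

    def test_design_evaluation_hr_half_combined_rule_beats_el_only(self):
        """With a protective allele, the joint EL&FEL top-quartile rule has
        PPV at least as high as the EL-only rule (direction check)."""
        cfg = dataclasses.replace(
            SMALL, n_founder_couples=10, causal_allele_freq=0.15
        )
        both = evaluate_selection_design(
            cfg, SelectionRule("el_fel_thresholds"), n_sim=15, seed=17,
            use_quartiles=True,
        )
        el_only = evaluate_selection_design(
            cfg,
            SelectionRule("el_fel_thresholds", el_min=3.0, fel_min=-1e9),
            n_sim=15, seed=17, use_quartiles=True,
        )
        tol = 2 * (both["ppv_se"] + el_only["ppv_se"])
        assert both["ppv"] >= el_only["ppv"] - tol
        # and the combined rule cannot be more sensitive
        assert both["sensitivity"] <= el_only["sensitivity"] + tol
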