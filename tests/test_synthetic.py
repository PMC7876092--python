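"""Generator correctness: copy-number laws, fluorescence model, assay designs."""
import dataclasses
import math

import numpy as np
import pytest
from scipy import stats

import vcnflow as vf
from vcnflow._errors import ParameterError, StructuralError
from vcnflow.synthetic import SortResult, simulate_serial_dilution, simulate_sort


def binomial_tol(p, n, k=4):
    return k * math.sqrt(p * (1 - p) / n)


class TestCopyNumbers:
    def test_zero_dose_gives_no_copies(self):
        truth = vf.simulate_copy_numbers(vf.SimConfig(n_cells=1000, lam=0.0, seed=1))
        assert truth.bulk_vcn == 0.0
        assert truth.fraction_positive == 0.0
        assert truth.real_vcn is None

    def test_poisson_positive_fraction_matches_analytic(self):
        truth = vf.simulate_copy_numbers(vf.SimConfig(n_cells=1_000_000, lam=1.0, seed=2))
        assert truth.fraction_positive == pytest.approx(1 - math.exp(-1), abs=0.002)
        assert truth.bulk_vcn == pytest.approx(1.0, abs=0.005)

    def test_sub_poisson_mixture_law(self):
        """Permissive-fraction mixture: enumerate the two-component law and
        compare fraction positive and mean copies among positives."""
        lam, pi, n = 1.0, 0.40, 1_000_000
        truth = vf.simulate_copy_numbers(
            vf.SimConfig(n_cells=n, lam=lam, permissive_fraction=pi, seed=3)
        )
        # brute-force expectation over the mixture: fraction of cells
        # permissive AND drawing k >= 1 from Poisson(lam/pi)
        ks = np.arange(1, 200)
        pmf = stats.poisson.pmf(ks, lam / pi)
        expected_fraction = pi * pmf.sum()
        expected_mean_positive = pi * np.sum(ks * pmf) / expected_fraction
        assert truth.fraction_positive == pytest.approx(expected_fraction, abs=0.002)
        assert truth.bulk_vcn == pytest.approx(lam, abs=0.01)
        mean_pos = truth.copies[truth.transduced].mean()
        assert mean_pos == pytest.approx(expected_mean_positive, rel=0.01)

    def test_sub_poisson_has_fewer_positives_than_poisson_at_equal_mean(self):
        n, lam = 100_000, 1.0
        full = vf.simulate_copy_numbers(vf.SimConfig(n_cells=n, lam=lam, seed=4))
        sub = vf.simulate_copy_numbers(
            vf.SimConfig(n_cells=n, lam=lam, permissive_fraction=0.5, seed=4)
        )
        assert sub.fraction_positive < full.fraction_positive
        assert sub.bulk_vcn == pytest.approx(full.bulk_vcn, abs=0.05)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            vf.SimConfig(n_cells=100, lam=-0.1)
        with pytest.raises(ParameterError):
            vf.SimConfig(n_cells=100, permissive_fraction=0.0)
        with pytest.raises(ParameterError):
            vf.SimConfig(n_cells=0)

    def test_reproducible_for_fixed_seed(self):
        cfg = vf.SimConfig(n_cells=5000, lam=0.8, permissive_fraction=0.7, seed=11)
        a = vf.simulate_copy_numbers(cfg)
        b = vf.simulate_copy_numbers(cfg)
        np.testing.assert_array_equal(a.copies, b.copies)
        ea = vf.simulate_flow_events(a, cfg)
        eb = vf.simulate_flow_events(b, cfg)
        assert ea.data.equals(eb.data)


class TestFlowEvents:
    def test_untransduced_signal_is_pure_background(self, control_threshold):
        cfg = vf.SimConfig(n_cells=200_000, lam=0.0, seed=5)
        events = vf.simulate_flow_events(vf.simulate_copy_numbers(cfg), cfg)
        g = vf.gate_sample(events, control_threshold)
        # false-positive budget of the 0.9999-quantile control gate
        assert g.fraction_positive <= 2e-4

    def test_signal_scales_with_mfi_per_copy(self):
        """With a flat background the copy-derived component doubles exactly
        when mfi_per_copy doubles (same seed, same noise stream)."""
        base = vf.SimConfig(n_cells=10_000, lam=1.0, background_sigma=0.0,
                            mfi_per_copy=40.0, seed=6)
        truth = vf.simulate_copy_numbers(base)
        bg = math.exp(base.background_mu)
        s1 = vf.simulate_flow_events(truth, base).channel("signal") - bg
        s2 = vf.simulate_flow_events(
            truth, dataclasses.replace(base, mfi_per_copy=80.0)
        ).channel("signal") - bg
        np.testing.assert_allclose(s2, 2.0 * s1, rtol=1e-12)

    @pytest.mark.parametrize("preset,target_ratio", [("MND", 8.9), ("PGK", 3.1)])
    def test_promoter_presets_reproduce_reported_mfi_ratios(
        self, control_threshold, preset, target_ratio
    ):
        cfg = vf.SimConfig(n_cells=200_000, lam=1.0, promoter_preset=preset, seed=7)
        truth = vf.simulate_copy_numbers(cfg)
        g = vf.gate_sample(vf.simulate_flow_events(truth, cfg), control_threshold)
        assert g.mfi_ratio == pytest.approx(target_ratio, rel=0.15)

    def test_saturation_caps_signal(self):
        cfg = vf.SimConfig(n_cells=50_000, lam=5.0, saturation_copies=2,
                           background_sigma=0.0, signal_cv=0.0, seed=8)
        truth = vf.simulate_copy_numbers(cfg)
        signal = vf.simulate_flow_events(truth, cfg).channel("signal")
        bg = math.exp(cfg.background_mu)
        assert signal.max() <= bg + 2 * cfg.mfi_per_copy + 1e-9

    def test_mismatched_marker_length_rejected(self):
        cfg = vf.SimConfig(n_cells=100, lam=1.0, seed=9)
        truth = vf.simulate_copy_numbers(cfg)
        with pytest.raises(StructuralError):
            vf.simulate_flow_events(truth, cfg, markers={"CD34": np.ones(50)})


class TestQpcrSimulation:
    def test_noiseless_unit_quantity_hits_reference_ct(self):
        m = vf.simulate_qpcr(1.0, sd_ct=0.0, ct_ref=24.0, efficiency=2.0)
        assert m.replicates == (24.0, 24.0, 24.0)

    def test_two_doublings_shift_two_cycles(self):
        m = vf.simulate_qpcr(4.0, sd_ct=0.0, ct_ref=24.0, efficiency=2.0)
        assert m.mean_ct == pytest.approx(22.0, abs=1e-12)

    def test_zero_quantity_is_censored(self):
        assert vf.simulate_qpcr(0.0).censored

    def test_replicate_noise_recovers_sd(self):
        """Mean of replicate variances over 1000 triplicate runs sits within
        Monte-Carlo bounds of sd_ct² (chi-square sampling of s²)."""
        sd = 0.2
        variances = [
            vf.simulate_qpcr(1.0, reps=3, sd_ct=sd, seed=1000 + i).sd_ct ** 2
            for i in range(1000)
        ]
        # Var(s²) = 2 sigma^4 / (n-1); 4-sigma band on the mean of 1000
        se = math.sqrt(2 / 2) * sd**2 / math.sqrt(1000)
        assert np.mean(variances) == pytest.approx(sd**2, abs=4 * se)


class TestSerialDilution:
    def test_expected_fractions_follow_halving(self, control_threshold):
        cfg = vf.SimConfig(n_cells=100_000, lam=1.0, seed=12)
        truth = vf.simulate_copy_numbers(cfg)
        events = vf.simulate_flow_events(truth, cfg)
        series = simulate_serial_dilution(truth, events, cfg, steps=6, ratio=0.5)
        assert series.factors == [1, 0.5, 0.25, 0.125, 0.0625, 0.03125, 0.015625]
        p0 = truth.fraction_positive
        for d, (_, sub_truth) in zip(series.factors, series.samples):
            expected = d * p0
            assert sub_truth.fraction_positive == pytest.approx(
                expected, abs=binomial_tol(expected, truth.n_cells)
            )
            assert sub_truth.bulk_vcn == pytest.approx(d * truth.bulk_vcn, rel=0.1)

    def test_undiluted_sample_is_identical(self):
        cfg = vf.SimConfig(n_cells=2000, lam=1.0, seed=13)
        truth = vf.simulate_copy_numbers(cfg)
        events = vf.simulate_flow_events(truth, cfg)
        series = simulate_serial_dilution(truth, events, cfg, steps=1)
        head_events, head_truth = series.samples[0]
        assert head_events.data.equals(events.data)
        np.testing.assert_array_equal(head_truth.copies, truth.copies)

    def test_invalid_ratio_rejected(self):
        cfg = vf.SimConfig(n_cells=10, lam=1.0, seed=14)
        truth = vf.simulate_copy_numbers(cfg)
        events = vf.simulate_flow_events(truth, cfg)
        with pytest.raises(ParameterError):
            simulate_serial_dilution(truth, events, cfg, ratio=1.5)


class TestSort:
    def _sample(self, n=200_000, lam=1.0, seed=15):
        # bright signal so the gate separates perfectly at purity 1
        cfg = vf.SimConfig(n_cells=n, lam=lam, mfi_per_copy=200.0, seed=seed)
        truth = vf.simulate_copy_numbers(cfg)
        return truth, vf.simulate_flow_events(truth, cfg)

    def test_perfect_sort_negative_subset_has_zero_vcn(self, control_threshold):
        truth, events = self._sample()
        res = simulate_sort(events, truth, control_threshold, purity=1.0, seed=1)
        # the control quantile admits ~1e-4 background false positives, which
        # carry zero copies and thus cannot raise the negative-side VCN
        assert res.negative.true_vcn == pytest.approx(0.0, abs=1e-3)

    def test_perfect_sort_positive_subset_matches_zero_truncated_mean(
        self, control_threshold
    ):
        truth, events = self._sample()
        res = simulate_sort(events, truth, control_threshold, purity=1.0, seed=1)
        assert res.positive.true_vcn == pytest.approx(
            1 / (1 - math.exp(-1)), abs=0.02
        )
        assert res.positive.fraction_of_bulk == pytest.approx(
            1 - math.exp(-1), abs=0.005
        )

    def test_impure_sort_contaminates_negative_side(self, control_threshold):
        truth, events = self._sample()
        res = simulate_sort(events, truth, control_threshold, purity=0.95, seed=1)
        # qualitative: the negative gate acquires a small but nonzero VCN,
        # as reported sorted-negative fractions do
        assert 0.0 < res.negative.true_vcn < 0.3

    def test_empty_subset_flagged(self, control_threshold):
        cfg = vf.SimConfig(n_cells=1000, lam=0.0, seed=16)
        truth = vf.simulate_copy_numbers(cfg)
        events = vf.simulate_flow_events(truth, cfg)
        res = simulate_sort(events, truth, threshold=events.channel("signal").max(),
                            purity=1.0, seed=2)
        assert res.positive.empty
        assert res.positive.true_vcn is None

    def test_purity_outside_range_rejected(self, control_threshold):
        truth, events = self._sample(n=100)
        with pytest.raises(ParameterError):
            simulate_sort(events, truth, control_threshold, purity=0.4)


class TestTitration:
    def test_fractions_follow_single_hit_curve(self):
        design = vf.TitrationDesign(doses=(10, 30, 100, 1000), alpha=5e-4)
        cfg = vf.SimConfig(n_cells=100_000, lam=1.0, seed=17)
        samples = vf.simulate_titration(design, cfg)
        for s in samples:
            expected = 1 - math.exp(-design.alpha * s.dose)
            assert s.truth.fraction_positive == pytest.approx(
                expected, abs=binomial_tol(max(expected, 1e-3), cfg.n_cells)
            )

    def test_low_dose_regime_is_linear(self):
        design = vf.TitrationDesign(doses=(1.0, 2.0), alpha=1e-4)
        for dose in design.doses:
            lam = design.alpha * dose
            assert 1 - math.exp(-lam) == pytest.approx(lam, rel=1e-3)

    def test_moi_conversion(self):
        design = vf.TitrationDesign(doses=(10, 1000), alpha=5e-4, moi_per_vp=0.00213)
        assert design.moi[0] == pytest.approx(0.0213)
        assert design.moi[1] == pytest.approx(2.13)

    def test_unsorted_doses_rejected(self):
        with pytest.raises(ParameterError):
            vf.TitrationDesign(doses=(100, 10), alpha=1e-3)
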