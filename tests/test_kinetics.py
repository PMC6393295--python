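"""Michaelis-Menten simulation and double-reciprocal recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nsun6kit.kinetics import (
    DEFAULT_SUBSTRATE_CONCS_UM,
    KineticsError,
    MichaelisMentenParams,
    ProgressCurve,
    RateDataset,
    SingularFitError,
    catalytic_efficiency,
    estimate_initial_rate,
    fit_lineweaver_burk,
    fit_michaelis_menten_nls,
    mm_rate,
    simulate_initial_rates,
    simulate_progress_curve,
)

WT = MichaelisMentenParams(kcat=4.30, km=0.43, enzyme_conc_nM=100.0)
U73G = MichaelisMentenParams(kcat=2.11, km=0.59, enzyme_conc_nM=100.0)


class TestMMRate:
    def test_half_saturation_identity(self):
        assert mm_rate(WT, WT.km) == pytest.approx(WT.vmax / 2)

    def test_zero_substrate_zero_rate(self):
        assert mm_rate(WT, 0.0) == 0.0

    def test_direct_arithmetic_oracle(self):
        # v = kcat * E * S / (Km + S), E in uM
        s = 40.0
        expected = 4.30 * (100.0 / 1000.0) * s / (0.43 + s)
        assert mm_rate(WT, s) == pytest.approx(expected, rel=1e-12)

    def test_negative_substrate_rejected(self):
        with pytest.raises(KineticsError):
            mm_rate(WT, -1.0)

    @settings(max_examples=50, deadline=None)
    @given(
        s1=st.floats(min_value=1e-3, max_value=1e3),
        s2=st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_monotone_and_bounded_by_vmax(self, s1, s2):
        lo, hi = sorted((s1, s2))
        v_lo, v_hi = mm_rate(WT, lo), mm_rate(WT, hi)
        assert v_lo <= v_hi <= WT.vmax

    def test_invalid_params_rejected(self):
        with pytest.raises(KineticsError):
            MichaelisMentenParams(kcat=0.0, km=1.0)


class TestSimulateInitialRates:
    def test_noiseless_rates_are_exact(self):
        data = simulate_initial_rates(WT, noise_sd_rel=0.0)
        expected = mm_rate(WT, np.array(DEFAULT_SUBSTRATE_CONCS_UM))
        assert np.allclose(data.rates, expected)

    def test_seeded_determinism(self):
        a = simulate_initial_rates(WT, noise_sd_rel=0.05, seed=7)
        b = simulate_initial_rates(WT, noise_sd_rel=0.05, seed=7)
        assert a.rates == b.rates
        c = simulate_initial_rates(WT, noise_sd_rel=0.05, seed=8)
        assert a.rates != c.rates

    def test_noise_is_mean_preserving(self):
        """Monte-Carlo mean of noisy rates converges to the noiseless
        rate at each concentration (multiplicative, unbiased)."""
        s = np.array(DEFAULT_SUBSTRATE_CONCS_UM)
        truth = mm_rate(WT, s)
        sims = np.array(
            [
                simulate_initial_rates(WT, noise_sd_rel=0.05, seed=seed).rates
                for seed in range(1000)
            ]
        )
        assert np.all(np.abs(sims.mean(axis=0) - truth) / truth < 0.01)

    def test_rates_stay_positive_under_heavy_noise(self):
        data = simulate_initial_rates(WT, noise_sd_rel=0.5, seed=3)
        assert all(r > 0 for r in data.rates)

    def test_duplicate_concentrations_rejected(self):
        with pytest.raises(KineticsError):
            RateDataset((1.0, 1.0, 2.0), (0.1, 0.1, 0.2), 100.0)


class TestEstimateInitialRate:
    def test_exact_linear_curve(self):
        curve = ProgressCurve(times=(2, 4, 6, 8), product=(0.2, 0.4, 0.6, 0.8))
        assert estimate_initial_rate(curve) == pytest.approx(0.1)

    def test_constant_product_zero_rate(self):
        curve = ProgressCurve(times=(2, 4, 6, 8), product=(0.5, 0.5, 0.5, 0.5))
        assert estimate_initial_rate(curve) == pytest.approx(0.0)

    def test_recovers_mm_rate_from_simulated_progress_curve(self):
        # at 40 uM the product formed over 8 min stays below 10% of S0
        s0 = 40.0
        curve = simulate_progress_curve(WT, s0=s0, times=(2, 4, 6, 8))
        assert curve.product[-1] / s0 < 0.10
        v = estimate_initial_rate(curve)
        assert v == pytest.approx(mm_rate(WT, s0), rel=0.02)

    def test_insufficient_points_rejected(self):
        with pytest.raises(KineticsError):
            estimate_initial_rate(ProgressCurve(times=(1, 2), product=(0.1, 0.2)))


class TestLineweaverBurk:
    @pytest.mark.parametrize("params", [WT, U73G], ids=["wild-type", "U73G"])
    def test_noiseless_recovery_is_exact(self, params):
        data = simulate_initial_rates(params, noise_sd_rel=0.0)
        fit = fit_lineweaver_burk(data)
        assert fit.km == pytest.approx(params.km, rel=1e-6)
        assert fit.kcat == pytest.approx(params.kcat, rel=1e-6)

    def test_rate_rescaling_rescales_kcat_only(self):
        data = simulate_initial_rates(WT, noise_sd_rel=0.0)
        scaled = RateDataset(
            data.substrate_concs,
            tuple(3.0 * r for r in data.rates),
            data.enzyme_conc_nM,
        )
        fit0 = fit_lineweaver_burk(data)
        fit3 = fit_lineweaver_burk(scaled)
        assert fit3.kcat == pytest.approx(3.0 * fit0.kcat, rel=1e-9)
        assert fit3.km == pytest.approx(fit0.km, rel=1e-9)

    def test_agrees_with_nonlinear_fit_on_noiseless_data(self):
        data = simulate_initial_rates(WT, noise_sd_rel=0.0)
        lb = fit_lineweaver_burk(data)
        nls = fit_michaelis_menten_nls(data)
        assert lb.km == pytest.approx(nls.km, rel=1e-6)
        assert lb.kcat == pytest.approx(nls.kcat, rel=1e-6)

    def test_full_output_diagnostics(self):
        data = simulate_initial_rates(WT, noise_sd_rel=0.0)
        _params, diag = fit_lineweaver_burk(data, full_output=True)
        assert diag["r_squared"] == pytest.approx(1.0)
        assert diag["intercept"] == pytest.approx(1.0 / WT.vmax, rel=1e-9)

    def test_too_few_concentrations_rejected(self):
        data = simulate_initial_rates(WT, substrate_concs=(0.5, 1, 2), noise_sd_rel=0.0)
        with pytest.raises(KineticsError):
            fit_lineweaver_burk(data)

    def test_nonpositive_rates_rejected(self):
        data = RateDataset((0.5, 1.0, 2.0, 4.0), (0.1, 0.0, 0.2, 0.3), 100.0)
        with pytest.raises(KineticsError):
            fit_lineweaver_burk(data)

    def test_singular_fit_detected(self):
        # rates decreasing in S make the reciprocal intercept negative
        data = RateDataset((0.5, 1.0, 2.0, 4.0), (0.4, 0.3, 0.2, 0.1), 100.0)
        with pytest.raises(SingularFitError):
            fit_lineweaver_burk(data)

    def test_median_recovery_under_noise(self):
        """5% multiplicative noise at the 8-point assay design: median
        recovered Km and kcat stay within 10% of truth."""
        kms, kcats = [], []
        for seed in range(200):
            data = simulate_initial_rates(WT, noise_sd_rel=0.05, seed=seed)
            fit = fit_lineweaver_burk(data)
            kms.append(fit.km)
            kcats.append(fit.kcat)
        assert abs(np.median(kms) - WT.km) / WT.km < 0.10
        assert abs(np.median(kcats) - WT.kcat) / WT.kcat < 0.10


class TestCatalyticEfficiency:
    @pytest.mark.parametrize(
        "params,expected",
        [
            (WT, 10.0),
            (U73G, 2.11 / 0.59),
            (MichaelisMentenParams(kcat=1.0, km=1.0), 1.0),
        ],
    )
    def test_ratio(self, params, expected):
        assert catalytic_efficiency(params) == pytest.approx(expected)
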