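"""Shielding arithmetic, TVL evaluation/fitting, distance model."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import barriermc as bm
from barriermc.analysis import (DistanceFit, ShieldingSpec, TransmissionCurve,
                                TVLFit2, TVLFit3, fit_attenuation_slope)
from barriermc.transport import SlabGeometry, SourceConfig, TransportConfig


class TestRequiredB:
    def test_conservative_vault_example(self):
        spec = ShieldingSpec(P=2e-5, W=1000.0, U=0.25, T_occ=1.0, d=6.3)
        assert bm.required_B(spec) == pytest.approx(3.2e-6, abs=0.05e-6)

    def test_identity_and_scaling(self):
        assert bm.required_B(ShieldingSpec(P=1.0, W=1.0, U=1.0, T_occ=1.0,
                                           d=1.0)) == 1.0
        b1 = bm.required_B(ShieldingSpec(P=2e-5, W=500, U=0.5, T_occ=1, d=5))
        b2 = bm.required_B(ShieldingSpec(P=2e-5, W=500, U=0.5, T_occ=1, d=10))
        assert b2 == pytest.approx(4 * b1)
        # invariant under joint scaling of P and W U T
        b3 = bm.required_B(ShieldingSpec(P=2e-4, W=5000, U=0.5, T_occ=1, d=5))
        assert b3 == pytest.approx(b1)

    def test_validation(self):
        with pytest.raises(ValueError):
            ShieldingSpec(P=2e-5, W=1000, U=1.5, T_occ=1, d=6.3)


class TestTVLEvaluators:
    FIT3 = TVLFit3(38.7, 26.8, 29.8)
    FIT2 = TVLFit2(37.4, 29.2)

    def test_decade_breakpoints_exact(self):
        assert bm.evaluate_B_tvl3(0.0, self.FIT3) == 1.0
        assert bm.evaluate_B_tvl3(38.7, self.FIT3) == pytest.approx(0.1, rel=1e-12)
        assert bm.evaluate_B_tvl3(38.7 + 26.8, self.FIT3) == pytest.approx(
            0.01, rel=1e-12)
        assert bm.evaluate_B_tvl2(37.4, self.FIT2) == pytest.approx(0.1, rel=1e-12)
        assert bm.evaluate_B_tvl2(37.4 + 29.2, self.FIT2) == pytest.approx(
            0.01, rel=1e-12)
        assert bm.evaluate_B_tvl2(37.4 + 2 * 29.2, self.FIT2) == pytest.approx(
            0.001, rel=1e-12)

    @settings(max_examples=60, deadline=None)
    @given(tvl1=st.floats(5, 100), tvl2=st.floats(5, 100), tvl3=st.floats(5, 100))
    def test_continuous_and_strictly_decreasing(self, tvl1, tvl2, tvl3):
        fit = TVLFit3(tvl1, tvl2, tvl3)
        t = np.linspace(0.0, 3 * (tvl1 + tvl2 + tvl3), 600)
        b = bm.evaluate_B_tvl3(t, fit)
        assert np.all(np.diff(b) < 0)
        for brk in (tvl1, tvl1 + tvl2):
            lo, hi = bm.evaluate_B_tvl3([brk - 1e-9, brk + 1e-9], fit)
            assert hi == pytest.approx(lo, rel=1e-6)


def _synthetic_curve(fit, noise=0.0, seed=0, t=None):
    t = np.arange(10.0, 211.0, 10.0) if t is None else t
    if isinstance(fit, TVLFit3):
        b = bm.evaluate_B_tvl3(t, fit)
    else:
        b = bm.evaluate_B_tvl2(t, fit)
    rng = np.random.default_rng(seed)
    if noise:
        b = b * np.exp(rng.normal(0.0, noise, t.size))
    return TransmissionCurve(t, b, np.maximum(noise, 1e-4) * b)


class TestTVLFitting:
    def test_noise_free_three_parameter_recovery(self):
        truth = TVLFit3(38.7, 26.8, 29.8)
        fit = bm.fit_tvl(_synthetic_curve(truth), model="three")
        assert fit.TVL1 == pytest.approx(truth.TVL1, rel=1e-6)
        assert fit.TVL2 == pytest.approx(truth.TVL2, rel=1e-6)
        assert fit.TVL3 == pytest.approx(truth.TVL3, rel=1e-6)
        assert fit.relative_residual < 1e-4

    def test_noise_free_two_parameter_recovery(self):
        truth = TVLFit2(37.4, 29.2)
        fit = bm.fit_tvl(_synthetic_curve(truth), model="two")
        assert fit.TVL1 == pytest.approx(truth.TVL1, rel=1e-6)
        assert fit.TVLe == pytest.approx(truth.TVLe, rel=1e-6)

    def test_noisy_recovery_unbiased_with_calibrated_errors(self):
        """5% lognormal noise, 50 replicates: median within 1 SD of truth and
        the reported sigma neither wildly over- nor under-covers."""
        truth = TVLFit3(42.5, 29.6, 35.1)
        fits, hits = [], 0
        for rep in range(50):
            fit = bm.fit_tvl(_synthetic_curve(truth, noise=0.05, seed=rep),
                             model="three")
            fits.append(fit)
            if abs(fit.TVL1 - truth.TVL1) < fit.sigma[0]:
                hits += 1
        med = np.median([f.TVL1 for f in fits])
        sd = np.std([f.TVL1 for f in fits])
        assert abs(med - truth.TVL1) < max(sd, 1e-9)
        assert 0.5 <= hits / 50 <= 0.99

    def test_preconditions(self):
        truth = TVLFit2(37.4, 29.2)
        short = _synthetic_curve(truth, t=np.array([10.0, 30.0, 50.0]))
        with pytest.raises(ValueError):
            bm.fit_tvl(short, model="two")
        curve = _synthetic_curve(truth)
        curve.sigma_B[:] = 0.0
        with pytest.raises(ValueError):
            bm.fit_tvl(curve, model="two")


class TestDensityScaling:
    def test_reference_factor(self):
        assert bm.density_scale_factor(2.29, 2.35) == pytest.approx(0.974, abs=5e-4)

    def test_identity_and_areal_conservation(self):
        fit = TVLFit3(38.7, 26.8, 29.8, sigma=(0.4, 0.5, 0.2))
        same = bm.scale_tvl_density(fit, 2.35, 2.35)
        assert same.TVL1 == fit.TVL1
        scaled = bm.scale_tvl_density(fit, 2.29, 2.35)
        assert scaled.TVL1 * 2.29 == pytest.approx(fit.TVL1 * 2.35, rel=1e-12)
        assert scaled.TVL1 > fit.TVL1  # lighter concrete needs more thickness


class TestComputeB:
    def _tally(self, concrete, kerma, counts=100, n=10_000, sigma=0.0):
        cfg = TransportConfig(
            source=SourceConfig(kind="pencil", mono_energy=6.0),
            slab=SlabGeometry(thickness=10.0, material=concrete), histories=n)
        from barriermc.transport import DetectorTally, TallyResult
        det = DetectorTally(dw_m=0.3, distance_m=6.3, radius_cm=50.0,
                            counts=counts, kerma=kerma, kerma_sigma=sigma)
        return TallyResult(config=cfg, n_histories=n, detectors=[det])

    def test_algebraic_inversion(self, concrete):
        d0 = 6.497e-14
        tally = self._tally(concrete, kerma=d0 * 1e-6 / 6.3**2)
        res = bm.compute_B(tally, d0)
        assert res.B == pytest.approx(1e-6, rel=1e-12)
        assert not res.upper_bound

    def test_linearity_in_dose_normalization(self, concrete):
        tally = self._tally(concrete, kerma=1e-20, sigma=1e-22)
        b1 = bm.compute_B(tally, 6e-14)
        b2 = bm.compute_B(tally, 12e-14)
        assert b2.B == pytest.approx(b1.B / 2)
        assert b2.sigma_B == pytest.approx(b1.sigma_B / 2)

    def test_zero_counts_yields_flagged_bound(self, concrete):
        res = bm.compute_B(self._tally(concrete, kerma=0.0, counts=0), 6e-14)
        assert res.upper_bound and res.B > 0

    def test_no_barrier_B_is_distance_independent(self, concrete):
        """Eq.-3-style B folds out the inverse square of a point source."""
        from barriermc.transport import DetectorSet
        cfg = TransportConfig(
            source=SourceConfig(kind="divergent_square", mono_energy=2.0,
                                field_side_at_iso=40.0),
            slab=SlabGeometry(thickness=0.0, material=concrete),
            detectors=DetectorSet(extra_axial_dw=(6.0,)),
            histories=150_000, rng_seed=41)
        res = bm.run_transport(cfg)
        d0 = 1.0e-13
        bs = [det.kerma * det.distance_m**2 / d0 for det in res.detectors]
        sig = [det.kerma_sigma * det.distance_m**2 / d0 for det in res.detectors]
        assert abs(bs[0] - bs[1]) < 3 * np.hypot(*sig)


class TestDistanceModel:
    FIT = DistanceFit(alpha=28.0, f0=0.02, d_s=6.0, d_w=0.3, f=2.4)

    def test_normalization_at_reference_point(self):
        assert float(bm.distance_profile_model(6.3, self.FIT)) == pytest.approx(
            1.0, rel=1e-12)

    def test_inverse_square_asymptotics(self):
        r = (bm.distance_profile_model(1000.0, self.FIT)
             / bm.distance_profile_model(2000.0, self.FIT))
        assert float(r) == pytest.approx(((2000 - 6.0) / (1000 - 6.0)) ** 2,
                                         rel=5e-3)

    def test_pseudo_source_exceeds_inverse_square_at_20m(self):
        ratio = (float(bm.distance_profile_model(20.0, self.FIT))
                 / float(bm.inverse_square_profile(20.0, 6.3)))
        assert ratio >= 2.0

    def test_model_domain(self):
        with pytest.raises(ValueError):
            bm.distance_profile_model(5.0, self.FIT)

    def test_exact_recovery_noise_free(self):
        d = np.linspace(6.5, 30.0, 12)
        y = bm.distance_profile_model(d, self.FIT)
        fit = bm.fit_distance_model(np.column_stack([d, y, 0.01 * y]))
        assert fit.alpha == pytest.approx(28.0, rel=1e-4)
        assert fit.f0 == pytest.approx(0.02, abs=1e-4)

    def test_noisy_recovery_of_alpha(self):
        d = np.linspace(6.5, 30.0, 12)
        y0 = bm.distance_profile_model(d, self.FIT)
        alphas = []
        for rep in range(50):
            rng = np.random.default_rng(rep)
            y = y0 * (1 + rng.normal(0, 0.05, d.size))
            alphas.append(bm.fit_distance_model(
                np.column_stack([d, y, 0.05 * y0])).alpha)
        assert np.median(alphas) == pytest.approx(28.0, rel=0.15)

    def test_model_beats_inverse_square_on_pseudo_source_profiles(self):
        """Residual comparison: the disc-source kernel describes an extended
        source profile far better than a point-source law."""
        d = np.linspace(6.5, 30.0, 12)
        rng = np.random.default_rng(4)
        y = bm.distance_profile_model(d, self.FIT) * (1 + rng.normal(0, 0.03, d.size))
        fit = bm.fit_distance_model(np.column_stack([d, y, 0.03 * y]))
        res_model = np.sum((bm.distance_profile_model(d, fit) - y) ** 2)
        res_isl = np.sum((bm.inverse_square_profile(d, 6.3) - y) ** 2)
        assert res_model < res_isl / 10


class TestAttenuationSlopeRegression:
    def test_recovers_poisson_decay_and_skips_empty_points(self):
        rng = np.random.default_rng(8)
        mu, n0 = 0.13, 1_000_000
        t = np.arange(10.0, 151.0, 10.0)
        counts = rng.poisson(n0 * np.exp(-mu * t))
        slope, se, ci = fit_attenuation_slope(t, counts, n0)
        assert slope == pytest.approx(mu, abs=3 * se + 1e-4)
        assert ci == pytest.approx(1.96 * se)

    def test_needs_enough_points(self):
        with pytest.raises(ValueError):
            fit_attenuation_slope([10, 20, 30], [5, 0, 0], 100)
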