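"""Transport engine: sampling, tallies, uncertainties, validation limits."""

import dataclasses

import numpy as np
import pytest

import barriermc as bm
from barriermc import _fastpath
from barriermc.transport import DetectorSet, SlabGeometry, SourceConfig, TransportConfig
from barriermc.xsec import CoefficientSet


def _pencil(energy, t, concrete, **kw):
    kw.setdefault("histories", 100_000)
    return TransportConfig(
        source=SourceConfig(kind="pencil", mono_energy=energy),
        slab=SlabGeometry(thickness=t, material=concrete), **kw)


class TestSelectInteraction:
    def test_no_pair_below_threshold(self, concrete, rng):
        procs = bm.select_interaction(concrete, np.full(20_000, 0.5), rng)
        assert not np.any(procs == "pair")

    def test_frequencies_match_mu_ratios(self, concrete, rng):
        cs = CoefficientSet(concrete)
        n = 200_000
        procs = bm.select_interaction(cs, np.full(n, 6.0), rng)
        expect = cs.process_probabilities(6.0).ravel()
        for name, p in zip(cs.processes, expect):
            obs = int((procs == name).sum())
            assert abs(obs - n * p) < 4 * np.sqrt(n * p * (1 - p)) + 1

    def test_equal_rates_at_crossing_energy(self, concrete, rng):
        e_x = bm.process_crossing_energy(concrete, "photoelectric", "incoherent")
        procs = bm.select_interaction(concrete, np.full(100_000, e_x), rng)
        n_pe = int((procs == "photoelectric").sum())
        n_c = int((procs == "incoherent").sum())
        assert abs(n_pe - n_c) < 5 * np.sqrt(n_pe + n_c)


class TestUncertainty:
    def test_constant_scores_give_zero(self):
        assert bm.estimate_uncertainty(np.full(100, 3.7)) == 0.0

    def test_bernoulli_closed_form(self, rng):
        p, n = 0.2, 50_000
        x = (rng.random(n) < p).astype(float)
        expect = np.sqrt(p * (1 - p) / n)
        assert bm.estimate_uncertainty(x) == pytest.approx(expect, rel=0.05)

    def test_agrees_with_batch_means(self, rng):
        x = rng.exponential(1.0, 100_000)
        sig = bm.estimate_uncertainty(x)
        batches = x.reshape(100, -1).mean(axis=1)
        sig_batch = batches.std(ddof=1) / 10.0
        assert sig / sig_batch == pytest.approx(1.0, abs=0.2)

    def test_needs_two_histories(self):
        with pytest.raises(ValueError):
            bm.estimate_uncertainty([1.0])


class TestDeterminismAndGeometry:
    def test_identical_seed_identical_tally(self, concrete):
        sp = bm.make_surrogate_spectrum(6.0)
        cfg = TransportConfig(
            source=SourceConfig(kind="divergent_square", spectrum=sp),
            slab=SlabGeometry(thickness=30.0, material=concrete),
            histories=20_000, rng_seed=77)
        a, b = bm.run_transport(cfg), bm.run_transport(cfg)
        assert a.principal.counts == b.principal.counts
        assert a.principal.kerma == b.principal.kerma
        assert np.array_equal(a.principal.spectrum_fluence,
                              b.principal.spectrum_fluence)

    def test_empty_slab_preserves_fluence(self, concrete):
        """With t = 0 no interaction can occur: detector fluence equals the
        incident fluence at that plane."""
        cfg = TransportConfig(
            source=SourceConfig(kind="parallel_circle", mono_energy=2.0,
                                radius=135.0),
            slab=SlabGeometry(thickness=0.0, material=concrete),
            histories=200_000, rng_seed=3)
        det = bm.run_transport(cfg).principal
        phi0 = 1.0 / (np.pi * 135.0**2)
        assert det.fluence == pytest.approx(phi0, abs=3 * det.fluence_sigma)
        assert bm.emergent_mean_energy(bm.run_transport(cfg)) == pytest.approx(2.0)

    def test_footprint_validation(self, concrete):
        with pytest.raises(ValueError):
            TransportConfig(
                source=SourceConfig(kind="parallel_circle", mono_energy=2.0,
                                    radius=1500.0),
                slab=SlabGeometry(thickness=10.0, material=concrete))

    def test_counting_estimate(self, concrete):
        """Tallied crossings agree with N0 * B * A_ic / A_b within factor 2."""
        cfg = TransportConfig(
            source=SourceConfig(kind="divergent_square", mono_energy=2.0,
                                field_side_at_iso=40.0),
            slab=SlabGeometry(thickness=30.0, material=concrete),
            histories=300_000, rng_seed=11)
        res = bm.run_transport(cfg)
        det = res.principal
        a_b = (40.0 * 6.3) ** 2  # beam area projected to the detector plane
        a_ic = np.pi * det.radius_cm**2
        B_f = det.fluence * a_b  # fluence transmission per source photon
        expect = res.n_histories * B_f * a_ic / a_b
        assert expect / 2 < det.counts < expect * 2


class TestScatterPhysics:
    def test_primary_only_exponential_limit(self, concrete):
        mu = float(bm.linear_attenuation(concrete, 6.0))
        for t in (20.0, 60.0):
            cfg = _pencil(6.0, t, concrete, scatter_mode="primary_only",
                          histories=200_000, rng_seed=5)
            det = bm.run_transport(cfg).principal
            p = np.exp(-mu * t)
            sig = np.sqrt(p * (1 - p) * cfg.histories)
            assert abs(det.counts - cfg.histories * p) < 4 * sig

    def test_annihilation_photons_in_spectrum(self, concrete):
        """Pair events must inject 0.511 MeV photons into the emergent beam."""
        cfg = _pencil(10.0, 25.0, concrete, histories=150_000, rng_seed=9)
        det = bm.run_transport(cfg).principal
        edges = det.spectrum_edges
        i511 = np.searchsorted(edges, 0.511) - 1
        window = det.spectrum_fluence[i511 - 1: i511 + 2].sum()
        neighbors = det.spectrum_fluence[i511 + 3: i511 + 6].sum()
        assert window > 2 * neighbors > 0

    def test_energy_never_above_source(self, concrete):
        cfg = _pencil(6.0, 40.0, concrete, histories=100_000, rng_seed=13)
        det = bm.run_transport(cfg).principal
        above = det.spectrum_fluence[det.spectrum_edges[:-1] >= 6.0]
        assert above.sum() == 0.0

    def test_beam_softens_then_detector_robust(self, concrete):
        """Broad-beam emergent mean energy far below the source energy, and
        halving the detector radius changes B only within statistics."""
        base = TransportConfig(
            source=SourceConfig(kind="divergent_square", mono_energy=2.0,
                                field_side_at_iso=40.0),
            slab=SlabGeometry(thickness=40.0, material=concrete),
            histories=400_000, rng_seed=21)
        res = bm.run_transport(base)
        assert bm.emergent_mean_energy(res) < 1.2  # multiple scatter dominates
        small = dataclasses.replace(
            base, detectors=DetectorSet(principal_radius=25.0), rng_seed=22)
        res_s = bm.run_transport(small)
        diff = abs(res.principal.kerma - res_s.principal.kerma)
        comb = np.hypot(res.principal.kerma_sigma, res_s.principal.kerma_sigma)
        assert diff < 3 * comb

    def test_air_attenuation_correction_factor(self, concrete, air):
        """The optional air correction rescales tallies by the straight-line
        exponential air path (source->slab plus slab->detector)."""
        base = _pencil(1.33, 30.0, concrete, scatter_mode="primary_only",
                       histories=50_000, rng_seed=19)
        on = dataclasses.replace(base, include_air_attenuation=True)
        f_off = bm.run_transport(base).principal.fluence
        f_on = bm.run_transport(on).principal.fluence
        mu_air = float(bm.linear_attenuation(air, 1.33))
        assert f_on / f_off == pytest.approx(np.exp(-mu_air * 600.0), rel=1e-9)

    def test_primary_only_beam_hardening(self, concrete):
        """The unscattered component of a polyenergetic beam hardens with
        depth (attenuation weighting by exp(-mu(E) t))."""
        sp = bm.make_surrogate_spectrum(4.0)
        means = []
        for i, t in enumerate((5.0, 20.0, 40.0)):
            cfg = TransportConfig(
                source=SourceConfig(kind="pencil", spectrum=sp),
                slab=SlabGeometry(thickness=t, material=concrete),
                histories=400_000, scatter_mode="primary_only", rng_seed=31 + i)
            means.append(bm.emergent_mean_energy(bm.run_transport(cfg)))
        assert means[0] < means[1] < means[2]


class TestSingleScatterKernels:
    def _cfg(self, concrete, **kw):
        kw.setdefault("rng_seed", 17)
        return TransportConfig(
            source=SourceConfig(kind="parallel_circle", mono_energy=2.0,
                                radius=135.0),
            slab=SlabGeometry(thickness=50.0, material=concrete),
            histories=400_000, scatter_mode="single_scatter_only",
            processes=("incoherent",), **kw)

    def test_compiled_and_generic_paths_agree(self, concrete):
        fast = bm.run_transport(self._cfg(concrete)).principal
        gen = bm.run_transport(self._cfg(concrete, force_generic=True)).principal
        diff = abs(fast.fluence - gen.fluence)
        assert diff < 3 * np.hypot(fast.fluence_sigma, gen.fluence_sigma)

    def test_vectorized_fallback_agrees(self, concrete, monkeypatch):
        fast = bm.run_transport(self._cfg(concrete)).principal
        monkeypatch.setattr(_fastpath, "HAVE_NUMBA", False)
        fb = bm.run_transport(self._cfg(concrete, rng_seed=18)).principal
        diff = abs(fast.fluence - fb.fluence)
        assert diff < 3 * np.hypot(fast.fluence_sigma, fb.fluence_sigma)

    def test_matches_quadrature(self, concrete):
        res = bm.run_transport(self._cfg(concrete)).principal
        geom = bm.SingleScatterGeometry(R=135.0, t=50.0, d_w=30.0, E=2.0,
                                        material=concrete)
        bq, _ = bm.single_scatter_transmission(geom)
        b_mc = res.fluence * np.pi * 135.0**2
        assert b_mc == pytest.approx(bq, abs=3 * res.fluence_sigma * np.pi * 135.0**2)
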