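"""Group optics, seasonal succession and microscopy counting noise."""

import numpy as np
import pytest

from mstaf.community_metrics import emission_ratio, ols_regress
from mstaf.synthetic_data import (
    CommunityState,
    SuccessionScenario,
    SyntheticSample,
    community_fluorescence,
    community_st_params,
    counting_scale_factor,
    default_group_models,
    simulate_microscopy,
    simulate_succession,
)


class TestDefaultModels:
    def test_algae_peak_blue(self, group_models):
        alg = group_models["algae"].sigma_spectrum
        assert alg[452] > alg[594]
        assert max(alg, key=alg.get) in (416, 452)

    def test_cyano_peak_orange(self, group_models):
        cy = group_models["cyanobacteria"].sigma_spectrum
        assert cy[594] > cy[452]
        assert max(cy, key=cy.get) in (594, 622)

    def test_cyano_allocates_more_to_psi(self, group_models):
        assert group_models["cyanobacteria"].psi_fraction_730 > \
            group_models["algae"].psi_fraction_730


class TestCommunityFluorescence:
    def test_zero_abundance(self, registry, group_models):
        state = CommunityState(0, {"algae": 0.0, "cyanobacteria": 0.0})
        assert community_fluorescence(state, group_models,
                                      registry["GOR"]) == (0.0, 0.0)

    def test_linearity_in_abundance(self, registry, group_models):
        s1 = CommunityState(0, {"algae": 1500.0, "cyanobacteria": 4000.0})
        s2 = CommunityState(0, {"algae": 3000.0, "cyanobacteria": 8000.0})
        fo1, fm1 = community_fluorescence(s1, group_models, registry["GOR"])
        fo2, fm2 = community_fluorescence(s2, group_models, registry["GOR"])
        assert fo2 == pytest.approx(2 * fo1, rel=1e-12)
        assert fm2 == pytest.approx(2 * fm1, rel=1e-12)

    def test_protocol_additivity(self, registry, group_models):
        """B + GOR at the same LED settings equals GORB (linear mixing)."""
        state = CommunityState(0, {"algae": 2000.0, "cyanobacteria": 6000.0})
        for band in (685, 730):
            fo_b, _ = community_fluorescence(state, group_models,
                                             registry["B"], band)
            fo_gor, _ = community_fluorescence(state, group_models,
                                               registry["GOR"], band)
            fo_gorb, _ = community_fluorescence(state, group_models,
                                                registry["GORB"], band)
            assert abs(fo_gorb - (fo_b + fo_gor)) < 1e-10 * fo_gorb

    def test_emission_ratio_increases_with_cyano_fraction(
            self, registry, group_models):
        total = 8000.0
        prev = -np.inf
        for f in np.linspace(0.0, 1.0, 21):
            state = CommunityState(0, {"algae": total * (1 - f),
                                       "cyanobacteria": total * f})
            fo685, _ = community_fluorescence(state, group_models,
                                              registry["GOR"], 685)
            fo730, _ = community_fluorescence(state, group_models,
                                              registry["GOR"], 730)
            ratio = emission_ratio(fo685, fo730)
            assert ratio > prev
            prev = ratio

    def test_effective_sigma_between_group_values(self, registry,
                                                  group_models):
        state = CommunityState(0, {"algae": 2000.0, "cyanobacteria": 6000.0})
        _, _, sig = community_st_params(state, group_models, registry["GOR"])
        e = 20990.0
        sig_groups = []
        for m in group_models.values():
            s = sum(led.intensity * m.sigma_spectrum[led.channel.center_wavelength]
                    for led in registry["GOR"].leds)
            sig_groups.append(s / e)
        assert min(sig_groups) <= sig <= max(sig_groups)


class TestSuccession:
    def test_noise_free_is_deterministic_and_smooth(self):
        sc = SuccessionScenario(seed=1, noise_sd_log=0.0)
        a = simulate_succession(sc)
        b = simulate_succession(SuccessionScenario(seed=99, noise_sd_log=0.0))
        for x, y in zip(a, b):
            assert x.abundance == y.abundance

    def test_seed_determinism(self):
        a = simulate_succession(SuccessionScenario(seed=5))
        b = simulate_succession(SuccessionScenario(seed=5))
        for x, y in zip(a, b):
            assert x.abundance == y.abundance

    def test_succession_shape(self):
        """Algae dominate the first date; cyanobacteria take over."""
        states = simulate_succession(SuccessionScenario(seed=0,
                                                        noise_sd_log=0.0))
        first, last = states[0], states[-1]
        assert first.abundance["algae"] > first.abundance["cyanobacteria"]
        assert last.abundance["cyanobacteria"] > last.abundance["algae"]

        def rel_cyano(s):
            return s.abundance["cyanobacteria"] / s.total

        assert rel_cyano(last) > rel_cyano(first)

    def test_date_count_validated(self):
        with pytest.raises(ValueError):
            SuccessionScenario(n_dates=2)


class TestMicroscopy:
    def test_scale_factor_is_ten_at_defaults(self):
        assert counting_scale_factor() == 10.0
        assert counting_scale_factor(50, 2.0) == 10.0
        assert counting_scale_factor(200, 1.0) == 5.0

    def test_estimates_are_multiples_of_ten(self):
        est = simulate_microscopy(2500.0, seed=3)
        assert est % 10.0 == 0.0

    def test_zero_density(self):
        assert simulate_microscopy(0.0, seed=1) == 0.0

    def test_poisson_moments(self):
        """Unbiased with variance 10 x density (Poisson scaling)."""
        rng = np.random.default_rng(8)
        density = 1000.0
        reps = np.array([simulate_microscopy(density, seed=rng)
                         for _ in range(10_000)])
        sd = reps.std(ddof=1)
        assert abs(reps.mean() - density) < 3.0 * sd / np.sqrt(reps.size)
        assert reps.var(ddof=1) == pytest.approx(10.0 * density, rel=0.10)


class TestEndToEnd:
    def test_pipeline_recovers_succession_signal(self, registry):
        """Succession -> traces -> fits -> ratios -> regression yields a
        positive, significant ratio-vs-cyanobacteria-fraction slope."""
        from mstaf.st_induction import fit_st_trace, simulate_st_trace

        states = simulate_succession(SuccessionScenario(seed=7))
        proto = registry["GOR"]
        ratios, fractions = [], []
        for state in states:
            sample = SyntheticSample(state=state)
            fos = {}
            for band in (685, 730):
                fo, fm, sig = sample.st_params(proto, band, 0.0)
                tr = simulate_st_trace(fo, fm, sig, proto,
                                       noise_sd=sample.noise_for(fm - fo),
                                       seed=sample.rng_for(proto, band, 7))
                fos[band] = fit_st_trace(tr, proto).F_o
            ratios.append(emission_ratio(fos[685], fos[730]))
            fractions.append(state.abundance["cyanobacteria"] / state.total)
        r = ols_regress(fractions, ratios)
        assert r.slope > 0
        assert r.p_value < 0.01
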