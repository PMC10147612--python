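"""Seeded synthetic-data generators: determinism, structure, recovery."""

import numpy as np
import pytest

from ferrispec import (
    DoseResponseDesign,
    MediumComposition,
    OxyCurveDesign,
    SyntheticConfig,
    TimecourseNoiseDesign,
    UptakeModel,
    fit_hill,
    fit_hyperbolic,
    gen_dose_response,
    gen_oxy_curve,
    gen_timecourse_observations,
    manifest,
    simulate,
)
from ferrispec.io import scenarios_from_config


class TestDoseResponseGenerator:
    def test_same_seed_is_bit_identical(self):
        a = gen_dose_response(SyntheticConfig(seed=7))
        b = gen_dose_response(SyntheticConfig(seed=7))
        assert np.array_equal(a.fe_conc, b.fe_conc)
        assert np.array_equal(a.hb, b.hb)

    def test_zero_noise_reproduces_the_model_exactly(self):
        cfg = SyntheticConfig(
            seed=0, dose_response=DoseResponseDesign(noise_sd=0.0)
        )
        data = gen_dose_response(cfg)
        d = cfg.dose_response
        expected = d.hb_max * data.fe_conc / (d.ec50 + data.fe_conc)
        assert data.hb == pytest.approx(expected, rel=1e-14)

    def test_design_covers_every_concentration(self):
        data = gen_dose_response(SyntheticConfig(seed=3))
        assert data.n_obs == 24
        assert set(np.unique(data.fe_conc)) == set(
            DoseResponseDesign().concentrations
        )

    def test_truth_recovered_by_hyperbolic_fit(self):
        cfg = SyntheticConfig(seed=11)
        fit = fit_hyperbolic(gen_dose_response(cfg))
        d = cfg.dose_response
        assert fit.hb_max == pytest.approx(d.hb_max, rel=0.10)
        assert fit.ec50 == pytest.approx(d.ec50, rel=0.25)

    def test_responses_never_negative(self):
        cfg = SyntheticConfig(
            seed=5, dose_response=DoseResponseDesign(noise_sd=1.0)
        )
        assert np.all(gen_dose_response(cfg).hb >= 0)


class TestOxyCurveGenerator:
    def test_zero_noise_gives_half_saturation_at_p50(self):
        cfg = SyntheticConfig(seed=0, oxy=OxyCurveDesign(noise_sd=0.0))
        curve = gen_oxy_curve(cfg)
        sat_at_p50 = np.interp(cfg.oxy.p50, curve.po2, curve.saturation)
        assert sat_at_p50 == pytest.approx(0.5, abs=1e-3)

    def test_clipping_keeps_saturation_in_unit_interval(self):
        cfg = SyntheticConfig(seed=2, oxy=OxyCurveDesign(noise_sd=0.5))
        curve = gen_oxy_curve(cfg)
        assert np.all(curve.saturation >= 0) and np.all(curve.saturation <= 1)

    def test_p50_recovery_within_two_percent_at_default_noise(self):
        errs = []
        for seed in range(20):
            cfg = SyntheticConfig(seed=seed)
            fit = fit_hill(gen_oxy_curve(cfg))
            errs.append(abs(fit.p50 - cfg.oxy.p50) / cfg.oxy.p50)
        assert np.median(errs) < 0.02


class TestTimecourseObservations:
    @staticmethod
    def course():
        comp = MediumComposition(tf_total=13e-6, fe_total=26e-6)
        return simulate(
            comp, uptake=UptakeModel(rate=1.7e-7), t_end=96, dt=12.0
        )

    def test_zero_noise_is_identity(self):
        cfg = SyntheticConfig(
            seed=0, timecourse_obs=TimecourseNoiseDesign(noise_sd=0.0)
        )
        tc = self.course()
        obs = gen_timecourse_observations(cfg, tc)
        truth = np.array(
            [[s.frac_apo, s.frac_mono, s.frac_holo] for s in tc.states]
        )
        assert obs[["frac_apo", "frac_mono", "frac_holo"]].to_numpy() == (
            pytest.approx(truth, abs=1e-12)
        )

    def test_fraction_triples_sum_to_one(self):
        cfg = SyntheticConfig(seed=4)
        obs = gen_timecourse_observations(cfg, self.course())
        sums = obs[["frac_apo", "frac_mono", "frac_holo"]].sum(axis=1)
        assert sums.to_numpy() == pytest.approx(np.ones(len(obs)), abs=1e-12)

    def test_scenario_ranking_survives_observation_noise(self):
        scen = scenarios_from_config(None)
        courses = [
            simulate(
                comp, chelator=chel, uptake=UptakeModel(rate=1.7e-7),
                t_end=96, dt=12.0, scenario_label=name,
            )
            for name, comp, chel in scen
        ]
        true_rank = np.argsort(
            [np.mean([s.frac_holo for s in tc.states]) for tc in courses]
        )
        agree = 0
        n_seeds = 30
        for seed in range(n_seeds):
            cfg = SyntheticConfig(
                seed=seed, timecourse_obs=TimecourseNoiseDesign(noise_sd=0.01)
            )
            means = [
                gen_timecourse_observations(cfg, tc)["frac_holo"].mean()
                for tc in courses
            ]
            agree += np.array_equal(np.argsort(means), true_rank)
        assert agree == n_seeds


class TestManifest:
    def test_manifest_identifies_config_changes(self):
        base = manifest(SyntheticConfig(seed=1))
        same = manifest(SyntheticConfig(seed=1))
        other = manifest(
            SyntheticConfig(seed=1, oxy=OxyCurveDesign(p50=24.2))
        )
        assert base == same
        assert base["config_hash"] != other["config_hash"]

    def test_regeneration_from_manifest_is_bit_identical(self):
        cfg = SyntheticConfig(seed=9)
        m = manifest(cfg)
        rebuilt = SyntheticConfig(
            seed=m["seed"],
            dose_response=DoseResponseDesign(
                **{k: tuple(v) if isinstance(v, list) else v
                   for k, v in m["config"]["dose_response"].items()}
            ),
            oxy=OxyCurveDesign(**m["config"]["oxy"]),
            timecourse_obs=TimecourseNoiseDesign(
                **m["config"]["timecourse_obs"]
            ),
        )
        a, b = gen_dose_response(cfg), gen_dose_response(rebuilt)
        assert np.array_equal(a.hb, b.hb)
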