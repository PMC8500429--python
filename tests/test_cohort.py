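"""Cohort synthesis: truncated parameter draws, Rician noise, normalisation."""

import numpy as np
import pytest
from scipy import stats

import dmridesign as dd
from dmridesign.cohort import cohort_from_frame, cohort_to_frame


def ivim_dist(label, means, sds):
    names = ("f", "d_slow", "d_fast")
    return dd.TissueDistribution(
        label, "ivim", dict(zip(names, means)), dict(zip(names, sds))
    )


class TestDrawTissueParameters:
    def test_zero_sd_gives_point_mass(self, rng):
        dist = ivim_dist("Healthy", (0.09, 0.35e-3, 123e-3), (0.0, 0.0, 0.0))
        draws = dd.draw_tissue_parameters(dist, 25, rng)
        assert len(draws) == 25
        assert all(p.f == 0.09 and p.d_slow == 0.35e-3 and p.d_fast == 123e-3
                   for p in draws)

    def test_truncation_matches_truncnorm_oracle(self, rng):
        # f = 0.07 +/- 0.08 puts ~19% of mass below 0; rejection must keep
        # every draw in [0, 1] with the truncated-Gaussian mean.
        mu, sd, n = 0.07, 0.08, 100_000
        dist = ivim_dist("Inflamed", (mu, 1.91e-3, 24.2e-3), (sd, 0.0, 0.0))
        f = np.array([p.f for p in dd.draw_tissue_parameters(dist, n, rng)])
        assert np.all((f >= 0) & (f <= 1))
        oracle = stats.truncnorm((0 - mu) / sd, (1 - mu) / sd, loc=mu, scale=sd)
        assert f.mean() == pytest.approx(oracle.mean(), abs=4 * oracle.std() / np.sqrt(n))
        assert f.std() == pytest.approx(oracle.std(), rel=0.02)

    def test_hopeless_distribution_raises(self, rng):
        dist = ivim_dist("bad", (-5.0, 1e-3, 0.1), (0.1, 0.0, 0.0))
        with pytest.raises(dd.ConfigurationError, match="acceptance"):
            dd.draw_tissue_parameters(dist, 10, rng)

    def test_mismatched_param_names_rejected(self):
        with pytest.raises(dd.ConfigurationError, match="parameter names"):
            dd.TissueDistribution("x", "ivim", {"f": 0.1}, {"f": 0.0})


class TestRicianNoise:
    def test_infinite_snr_is_identity(self, rng):
        s = np.array([1.0, 0.7, 0.3])
        np.testing.assert_array_equal(dd.add_rician_noise(s, np.inf, rng), s)

    def test_rayleigh_moments_at_zero_signal(self, rng):
        # true signal 0, sigma 1 -> Rayleigh: mean sigma*sqrt(pi/2), var (2-pi/2)sigma^2
        draws = dd.add_rician_noise(np.zeros(1_000_000), 1.0, rng)
        assert draws.mean() == pytest.approx(np.sqrt(np.pi / 2), rel=5e-3)
        assert draws.var() == pytest.approx(2 - np.pi / 2, rel=1e-2)

    def test_rician_mean_matches_scipy_rice(self, rng):
        sigma = 1 / 20
        draws = dd.add_rician_noise(np.ones(1_000_000), 20.0, rng)
        expected = stats.rice.mean(b=1.0 / sigma, scale=sigma)
        assert draws.mean() == pytest.approx(expected, rel=5e-3)

    def test_high_snr_sd_approaches_sigma(self, rng):
        # near S=1 and SNR >= 100 the Rician is essentially Gaussian
        snr = 150.0
        draws = dd.add_rician_noise(np.ones(500_000), snr, rng)
        assert draws.std() == pytest.approx(1 / snr, rel=0.02)

    def test_rejects_bad_snr_and_signal(self, rng):
        with pytest.raises(dd.InputValidationError):
            dd.add_rician_noise(np.ones(3), 0.0, rng)
        with pytest.raises(dd.InputValidationError):
            dd.add_rician_noise(np.array([-0.1]), 20.0, rng)


@pytest.fixture
def base_spec():
    proto = dd.AcquisitionProtocol(
        b_values=[0, 10, 20, 40, 80, 100, 200, 400, 600], snr=20
    )
    tissues = (
        ivim_dist("Healthy", (0.09, 0.35e-3, 123e-3), (0.0, 0.0, 0.0)),
        ivim_dist("Chronic", (0.12, 0.35e-3, 123e-3), (0.0, 0.0, 0.0)),
    )
    return dd.CohortSpec(tissues=tissues, n_per_tissue=50, protocol=proto, seed=7)


class TestSynthesizeCohort:
    def test_structure_and_labels(self, base_spec):
        cohort = dd.synthesize_cohort(base_spec)
        assert len(cohort) == 100
        assert {r.tissue_label for r in cohort} == {"Healthy", "Chronic"}
        nb = base_spec.protocol.n_measurements
        assert all(r.signal.shape == (nb,) for r in cohort)
        assert all(np.all(np.isfinite(r.signal)) & np.all(r.signal >= 0)
                   for r in cohort)

    def test_noise_free_limit_recovers_model_curve(self, base_spec):
        import dataclasses
        proto = dd.AcquisitionProtocol(b_values=base_spec.protocol.b_values, snr=1e9)
        spec = dataclasses.replace(base_spec, protocol=proto)
        cohort = dd.synthesize_cohort(spec)
        for rec in cohort[:5]:
            expected = dd.ivim_signal(rec.true_params, proto.b_values)
            np.testing.assert_allclose(rec.signal, expected, rtol=1e-6)

    def test_deterministic_given_seed(self, base_spec):
        a = dd.synthesize_cohort(base_spec)
        b = dd.synthesize_cohort(base_spec)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.signal, rb.signal)
            assert ra.true_params == rb.true_params

    def test_normalised_b0_is_one(self, base_spec):
        cohort = dd.synthesize_cohort(base_spec)
        b0 = base_spec.protocol.b0_index
        assert all(r.signal[b0] == 1.0 for r in cohort)

    def test_rician_floor_inflates_high_b_mean(self, base_spec):
        # at high b the noise floor pushes the mean magnitude above the
        # noise-free curve
        import dataclasses
        spec = dataclasses.replace(base_spec, n_per_tissue=5000)
        cohort = [r for r in dd.synthesize_cohort(spec) if r.tissue_label == "Healthy"]
        signals = np.array([r.signal for r in cohort])
        clean = dd.ivim_signal(cohort[0].true_params, spec.protocol.b_values)
        assert signals[:, -1].mean() > clean[-1]

    def test_cohort_frame_round_trip(self, base_spec):
        cohort = dd.synthesize_cohort(base_spec)
        frame = cohort_to_frame(cohort, base_spec.protocol)
        back = cohort_from_frame(frame, base_spec.protocol)
        assert len(back) == len(cohort)
        for ra, rb in zip(cohort, back):
            assert ra.tissue_label == rb.tissue_label
            np.testing.assert_allclose(ra.signal, rb.signal, rtol=1e-12)

    def test_identical_labels_rejected(self, base_spec):
        t = base_spec.tissues[0]
        with pytest.raises(dd.ConfigurationError, match="distinct"):
            dd.CohortSpec(tissues=(t, t), n_per_tissue=10,
                          protocol=base_spec.protocol, seed=1)
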