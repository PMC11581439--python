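import numpy as np
import pytest

from crowdscope.photophysics import (
    DecayTrace,
    PerrinInputs,
    calibrate_crowder,
    fit_anisotropy_decay,
    fit_lifetime_decay,
    perrin_steady_state,
    phasor_of_lifetime,
    phasor_transform,
    reconstruct_anisotropy_map,
    estimate_instrumental_scale,
    rotational_correlation_time,
    strickler_berg_scale,
)
from crowdscope.synthetic import synth_traces


class TestAnisotropyDecayFit:
    def test_noiseless_exact(self):
        trace, truth = synth_traces("anisotropy_decay")
        fit = fit_anisotropy_decay(trace)
        assert fit.r0 == pytest.approx(truth["r0"], rel=1e-8)
        assert fit.theta_c == pytest.approx(truth["theta_c"], rel=1e-8)

    def test_poisson_recovery_unbiased(self):
        r0s, thetas = [], []
        for seed in range(30):
            trace, truth = synth_traces("anisotropy_decay", noise="poisson", seed=seed)
            fit = fit_anisotropy_decay(trace)
            r0s.append(fit.r0 / truth["r0"])
            thetas.append(fit.theta_c / truth["theta_c"])
        assert np.mean(r0s) == pytest.approx(1.0, abs=0.05)
        assert np.mean(thetas) == pytest.approx(1.0, abs=0.05)

    def test_flat_trace_flagged_non_rotating(self):
        t = np.linspace(0, 12, 100)
        trace = DecayTrace(t=t, counts=np.full(100, 0.35), kind="anisotropy")
        fit = fit_anisotropy_decay(trace)
        assert fit.non_rotating
        assert np.isinf(fit.theta_c)
        assert fit.r0 == pytest.approx(0.35, rel=1e-6)

    def test_requires_anisotropy_kind(self):
        trace, _ = synth_traces("lifetime_decay")
        with pytest.raises(ValueError, match="anisotropy"):
            fit_anisotropy_decay(trace)


class TestLifetimeFit:
    def test_noiseless_exact(self):
        trace, truth = synth_traces("lifetime_decay")
        fit = fit_lifetime_decay(trace)
        assert fit.tau == pytest.approx(truth["tau"], rel=1e-8)

    def test_offset_does_not_bias_tau(self):
        clean, truth = synth_traces("lifetime_decay")
        shifted, _ = synth_traces("lifetime_decay", params={"offset": 50.0})
        fit = fit_lifetime_decay(shifted)
        assert fit.tau == pytest.approx(truth["tau"], rel=0.01)
        assert fit.offset == pytest.approx(50.0, rel=0.01)

    def test_two_component_returns_intermediate_with_structured_residual(self):
        t = np.linspace(0, 20, 400)
        y = 7000 * np.exp(-t / 1.5) + 3000 * np.exp(-t / 4.0)
        fit = fit_lifetime_decay(DecayTrace(t=t, counts=y, kind="intensity"))
        assert 1.5 < fit.tau < 4.0
        # single-exponential misfit leaves sign-correlated residual runs
        signs = np.sign(fit.residual[np.abs(fit.residual) > 1e-9])
        flips = np.sum(signs[1:] != signs[:-1])
        assert flips < 0.2 * signs.size


class TestPerrin:
    def test_limits(self):
        assert perrin_steady_state(0.38, 0.0, 14.0) == 0.38
        assert perrin_steady_state(0.38, 14.0, 14.0) == pytest.approx(0.19)

    def test_hand_value(self):
        assert perrin_steady_state(0.38, 2.6, 14.0) == pytest.approx(0.32049, abs=1e-5)

    def test_nonpositive_theta_rejected(self):
        with pytest.raises(ValueError):
            perrin_steady_state(0.38, 2.6, 0.0)

    def test_rotational_correlation_time_units(self):
        # water-like viscosity, ~4 nm^3 protein at room temperature -> ns scale
        theta = rotational_correlation_time(
            PerrinInputs(eta=1e-3, vol_h=4e-26, temperature=293.0)
        )
        assert theta == pytest.approx(1e-3 * 4e-26 / (1.380649e-23 * 293) * 1e9)

    def test_map_reconstruction_matches_scalar(self):
        shape = (8, 8)
        out = reconstruct_anisotropy_map(
            np.full(shape, 0.38), np.full(shape, 2.6), np.full(shape, 14.0)
        )
        np.testing.assert_allclose(out, perrin_steady_state(0.38, 2.6, 14.0))

    def test_scale_factor_applied_exactly(self):
        shape = (4, 4)
        base = reconstruct_anisotropy_map(
            np.full(shape, 0.38), np.full(shape, 2.6), np.full(shape, 14.0)
        )
        scaled = reconstruct_anisotropy_map(
            np.full(shape, 0.38), np.full(shape, 2.6), np.full(shape, 14.0), scale=0.9
        )
        np.testing.assert_allclose(scaled, 0.9 * base)

    def test_instrumental_scale_estimated(self, rng):
        recon = rng.uniform(0.2, 0.3, 100)
        measured = 0.87 * recon
        assert estimate_instrumental_scale(recon, measured) == pytest.approx(0.87)


class TestStricklerBerg:
    def test_identity_and_hand_value(self):
        assert strickler_berg_scale(2.6, 1.33, 1.33) == 2.6
        assert strickler_berg_scale(2.6, 1.33, 1.40) == pytest.approx(2.3465, abs=1e-4)

    def test_doubling_index_quarters_tau(self):
        assert strickler_berg_scale(2.6, 1.2, 2.4) == pytest.approx(2.6 / 4)

    def test_swapped_indices_invert(self):
        tau2 = strickler_berg_scale(2.6, 1.33, 1.40)
        assert strickler_berg_scale(tau2, 1.40, 1.33) == pytest.approx(2.6)


class TestPhasor:
    def test_monoexponential_on_semicircle_and_closed_form(self):
        tau = 2.6
        t = np.linspace(0, 30 * tau, 1_200_001)
        omega = 2 * np.pi / (100 * tau)
        pt = phasor_transform(
            DecayTrace(t=t, counts=np.exp(-t / tau), kind="intensity"), omega
        )
        wt = omega * tau
        assert pt.gcoord == pytest.approx(1 / (1 + wt**2), abs=1e-6)
        assert pt.scoord == pytest.approx(wt / (1 + wt**2), abs=1e-6)
        assert (pt.gcoord - 0.5) ** 2 + pt.scoord**2 == pytest.approx(0.25, abs=1e-6)

    def test_delta_decay_at_origin_corner(self):
        t = np.linspace(0, 10, 1000)
        counts = np.zeros(1000)
        counts[0] = 1.0
        pt = phasor_transform(DecayTrace(t=t, counts=counts, kind="intensity"), 0.5)
        assert (pt.gcoord, pt.scoord) == (1.0, 0.0)

    def test_mixture_lies_on_chord(self):
        tau_a, tau_b = 1.0, 5.0
        omega = 2 * np.pi / 200.0
        t = np.linspace(0, 150, 300_001)
        ya = np.exp(-t / tau_a) / tau_a
        yb = np.exp(-t / tau_b) / tau_b
        mix = phasor_transform(DecayTrace(t=t, counts=ya + yb, kind="intensity"), omega)
        pa = phasor_of_lifetime(tau_a, omega)
        pb = phasor_of_lifetime(tau_b, omega)
        # phasors are intensity-weighted linear: equal-intensity mixture sits
        # at the chord midpoint
        assert mix.gcoord == pytest.approx((pa.gcoord + pb.gcoord) / 2, abs=1e-4)
        assert mix.scoord == pytest.approx((pa.scoord + pb.scoord) / 2, abs=1e-4)

    def test_zero_intensity_rejected(self):
        t = np.linspace(0, 10, 50)
        with pytest.raises(ValueError, match="zero total"):
            phasor_transform(DecayTrace(t=t, counts=np.zeros(50), kind="intensity"))


class TestCrowderCalibration:
    def test_exact_line(self):
        r = np.array([0.17, 0.19, 0.21, 0.25])
        c = 10.0 * (r - 0.17)
        cal = calibrate_crowder(c, r)
        assert cal.m == pytest.approx(10.0)
        assert cal.alpha_r == pytest.approx(0.17)
        assert cal.r_squared == pytest.approx(1.0)

    def test_noisy_line_within_five_percent(self, rng):
        c = np.linspace(0, 300, 12)
        r = c / 1500.0 + 0.17 + rng.normal(0, 0.001, c.size)
        cal = calibrate_crowder(c, r)
        assert cal.m == pytest.approx(1500.0, rel=0.05)
        assert cal.alpha_r == pytest.approx(0.17, rel=0.05)

    def test_roundtrip_maps(self):
        cal = calibrate_crowder([0.0, 100.0, 200.0], [0.17, 0.18, 0.19])
        np.testing.assert_allclose(cal.concentration(cal.anisotropy([50.0])), [50.0])

    def test_degenerate_abscissa(self):
        with pytest.raises(ValueError, match="degenerate"):
            calibrate_crowder([5.0, 5.0, 5.0], [0.1, 0.2, 0.3])
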