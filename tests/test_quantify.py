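"""Fermi deconvolution: impulse response, convolution model, fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import perftwin as pt
from perftwin.errors import InvalidConfigError, NotConvergedError
from perftwin.experiments import acquire_dual_bolus


class TestFermiShape:
    P = pt.FermiParams(F=0.15, k=0.2, tau_d=2.0, tau_0=4.0)

    def test_zero_before_delay(self):
        t = np.linspace(0.0, 1.9, 20)
        assert np.all(pt.fermi_h(t, self.P) == 0.0)

    def test_height_at_onset_equals_F(self):
        assert pt.fermi_h(self.P.tau_d, self.P) == pytest.approx(self.P.F)

    def test_decays_to_zero(self):
        assert pt.fermi_h(1e4, self.P) == pytest.approx(0.0, abs=1e-12)

    def test_negative_parameters_rejected(self):
        with pytest.raises(InvalidConfigError):
            pt.FermiParams(F=-0.1, k=0.1, tau_d=0.0, tau_0=0.0)


class TestModelTissue:
    def test_impulse_returns_sampled_h(self):
        dt = 1.0
        n = 60
        aif = np.zeros(n)
        aif[0] = 1.0 / dt
        p = pt.FermiParams(0.1, 0.15, 1.0, 3.0)
        q = pt.model_tissue(aif, p, dt)
        np.testing.assert_allclose(q, pt.fermi_h(np.arange(n) * dt, p), atol=1e-14)

    def test_linear_in_aif_amplitude(self, smooth_aif):
        p = pt.FermiParams(0.1, 0.15, 1.0, 3.0)
        q1 = pt.model_tissue(smooth_aif.values, p, 1.0)
        q3 = pt.model_tissue(3.0 * smooth_aif.values, p, 1.0)
        np.testing.assert_allclose(q3, 3.0 * q1, rtol=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        n=st.integers(3, 50),
        seed=st.integers(0, 2**31 - 1),
        dt=st.sampled_from([0.5, 1.0, 2.0]),
    )
    def test_matches_brute_force_convolution(self, n, seed, dt):
        rng = np.random.default_rng(seed)
        aif = rng.uniform(0.0, 5.0, n)
        p = pt.FermiParams(*rng.uniform([0.0, 0.0, 0.0, 0.0], [0.5, 1.0, 5.0, 8.0]))
        q = pt.model_tissue(aif, p, dt)
        brute = np.zeros(n)
        for i in range(n):
            for j in range(i + 1):
                brute[i] += dt * aif[j] * pt.fermi_h((i - j) * dt, p)
        np.testing.assert_allclose(q, brute, rtol=1e-10, atol=1e-12)


def _as_curves(aif_vals, tis_vals, dt=1.0):
    t = np.arange(len(aif_vals)) * dt
    return (pt.SignalCurve("aif", t, np.maximum(aif_vals, 0)),
            pt.SignalCurve("tis", t, np.maximum(tis_vals, 0)))


class TestFitFermi:
    def test_noiseless_self_recovery(self, smooth_aif):
        true = pt.FermiParams(F=0.12, k=0.18, tau_d=1.0, tau_0=3.5)
        q = pt.model_tissue(smooth_aif.values, true, 1.0, oversample=4)
        aif, tis = _as_curves(smooth_aif.values, q)
        res = pt.fit_fermi(aif, tis)
        assert res.converged
        assert res.params.F == pytest.approx(true.F, rel=1e-4)
        assert res.perfusion_ml_ml_min == pytest.approx(true.F * 60.0, rel=1e-4)

    def test_zero_tissue_gives_zero_flow(self, smooth_aif):
        aif, tis = _as_curves(smooth_aif.values, np.zeros_like(smooth_aif.values))
        res = pt.fit_fermi(aif, tis)
        assert res.converged
        assert res.params.F == pytest.approx(0.0, abs=1e-6)

    def test_scale_invariance(self, smooth_aif):
        true = pt.FermiParams(F=0.1, k=0.15, tau_d=1.0, tau_0=2.0)
        q = pt.model_tissue(smooth_aif.values, true, 1.0, oversample=4)
        a1, t1 = _as_curves(smooth_aif.values, q)
        a2, t2 = _as_curves(smooth_aif.values * 37.0, q * 37.0)
        r1 = pt.fit_fermi(a1, t1)
        r2 = pt.fit_fermi(a2, t2)
        assert r2.perfusion_ml_ml_min == pytest.approx(r1.perfusion_ml_ml_min, rel=1e-4)

    def test_delay_absorbed_into_tau_d(self, smooth_aif):
        true = pt.FermiParams(F=0.1, k=0.15, tau_d=1.0, tau_0=2.0)
        q = pt.model_tissue(smooth_aif.values, true, 1.0, oversample=4)
        shifted = np.concatenate([np.zeros(2), q[:-2]])  # tissue delayed by +2 s
        a1, t1 = _as_curves(smooth_aif.values, q)
        a2, t2 = _as_curves(smooth_aif.values, shifted)
        r1 = pt.fit_fermi(a1, t1)
        r2 = pt.fit_fermi(a2, t2)
        assert abs(r2.perfusion_ml_ml_min - r1.perfusion_ml_ml_min) < 0.05 * r1.perfusion_ml_ml_min

    def test_mismatched_grids_rejected(self, smooth_aif):
        t2 = np.arange(0.0, 60.0, 2.0)
        tis = pt.SignalCurve("tis", t2, np.ones_like(t2))
        with pytest.raises(InvalidConfigError):
            pt.fit_fermi(smooth_aif, tis)


class TestPipelineRecovery:
    @pytest.mark.parametrize("rate", [1.0, 5.0, 10.0])
    def test_noiseless_monoexponential_recovery_within_10_percent(
        self, rate, calibrated_model, seq
    ):
        """Simulated tissue follows the compartment's mono-exponential response;
        the Fermi read-off at onset should land within 10% of gold standard."""
        cfg = pt.reference_circuit(3.0, 10.0, rate)
        acq = acquire_dual_bolus(cfg, pt.InjectionProtocol(0.01), seq, calibrated_model)
        res = pt.quantify_dual_bolus(acq, seq, calibrated_model, roi="myo_left")["myo_left"]
        assert res.converged
        assert res.perfusion_ml_ml_min == pytest.approx(rate, rel=0.10)


class TestEstimatePerfusion:
    def test_unit_conversion(self):
        res = pt.DeconvolutionResult(
            params=pt.FermiParams(10.0 / 60.0, 0.1, 0.0, 0.0),
            perfusion_ml_ml_min=10.0, residual_rms=0.0, converged=True, n_iter=1,
        )
        assert pt.estimate_perfusion(res) == pytest.approx(10.0)

    def test_unconverged_raises_with_diagnostics(self):
        res = pt.DeconvolutionResult(
            params=pt.FermiParams(0.0, 0.0, 0.0, 0.0),
            perfusion_ml_ml_min=float("nan"), residual_rms=float("inf"),
            converged=False, n_iter=123,
        )
        with pytest.raises(NotConvergedError, match="123"):
            pt.estimate_perfusion(res)


class TestAssembleAif:
    def make_acq(self, dose_ratio=10.0):
        t = np.arange(0.0, 60.0, 1.0)
        pre = pt.SignalCurve("aorta", t, np.where(t > 10, 1335.0 * np.exp(-((t - 20) / 6) ** 2), 0.0))
        tis = pt.SignalCurve("myo", t, np.zeros_like(t))
        return pt.DualBolusAcquisition(pre, {"myo": tis}, dose_ratio)

    def test_dose_ratio_scaling(self):
        aif = pt.assemble_aif(self.make_acq(10.0))
        assert aif.values.max() == pytest.approx(13350.0, rel=1e-6)

    def test_unit_ratio_is_identity(self):
        acq = self.make_acq(1.0)
        aif = pt.assemble_aif(acq)
        np.testing.assert_allclose(aif.values, acq.prebolus_aif.baseline_subtracted())

    def test_zero_curve_stays_zero(self):
        t = np.arange(0.0, 30.0, 1.0)
        acq = pt.DualBolusAcquisition(
            pt.SignalCurve("a", t, np.zeros_like(t)),
            {"m": pt.SignalCurve("m", t, np.zeros_like(t))}, 10.0,
        )
        assert np.all(pt.assemble_aif(acq).values == 0.0)

    def test_mismatched_sampling_rejected(self):
        t1 = np.arange(0.0, 30.0, 1.0)
        t2 = np.arange(0.0, 30.0, 2.0)
        with pytest.raises(InvalidConfigError):
            pt.DualBolusAcquisition(
                pt.SignalCurve("a", t1, np.zeros_like(t1)),
                {"m": pt.SignalCurve("m", t2, np.zeros_like(t2))}, 10.0,
            )
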