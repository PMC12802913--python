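"""Correlation functions, spectral densities and relaxation rates.

The independent oracle for the rate expressions is a literal symbol-by-
symbol re-evaluation of the dipolar + CSA formulas, written separately
from the library implementation.
"""

import math

import numpy as np
import pytest

from taildyn.constants import GAMMA_H, GAMMA_N, HBAR, MU0_OVER_4PI, SpinSystemConstants
from taildyn.relaxometry import (
    CorrelationFunction,
    SpectralDensityModel,
    VectorSeries,
    apply_tumbling,
    compare_to_experiment,
    fit_triexponential,
    p2_autocorrelation,
    relaxation_rates,
    residue_tau_c,
)
from taildyn.synthetic import (
    ConeSpec,
    RotDiffSpec,
    cone_order_parameter,
    gen_cone_vectors,
    gen_rotdiff_vectors,
)


def oracle_rates(J, nu_H=600.13e6, r_NH=1.02, csa=-172.0):
    """Independent evaluation of the dipolar+CSA rate expressions."""
    gH, gN = GAMMA_H, GAMMA_N
    wH = 2 * math.pi * nu_H
    wN = 2 * math.pi * nu_H * abs(gN / gH)
    d = MU0_OVER_4PI * HBAR * gH * gN / (r_NH * 1e-10) ** 3
    c = wN * csa * 1e-6 / math.sqrt(3)
    R1 = (d**2 / 4) * (J(wH - wN) + 3 * J(wN) + 6 * J(wH + wN)) + c**2 * J(wN)
    R2 = (d**2 / 8) * (4 * J(0) + J(wH - wN) + 3 * J(wN) + 6 * J(wH) + 6 * J(wH + wN)) + (
        c**2 / 6
    ) * (4 * J(0) + 3 * J(wN))
    noe = 1 + (d**2 / 4) * (gH / gN) * (6 * J(wH + wN) - J(wH - wN)) / R1
    return R1, R2, noe


def lorentzian(tau):
    return lambda w: 0.4 * tau / (1 + (w * tau) ** 2)


class TestP2Autocorrelation:
    def test_static_vector_is_unity(self):
        v = np.tile([0.0, 0.0, 1.0], (100, 1))
        corr = p2_autocorrelation(VectorSeries(1, v, 1e-12), n_chunks=4, max_lag_fraction=1.0)
        assert np.allclose(corr.values, 1.0, atol=1e-12)

    def test_independent_uniform_vectors_decorrelate(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(40_000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        corr = p2_autocorrelation(VectorSeries(1, v, 1e-12), n_chunks=20, max_lag_fraction=0.02)
        nonzero = corr.lags > 0
        assert np.all(np.abs(corr.values[nonzero]) < 3 * corr.stderr[nonzero])

    def test_matches_closed_form_for_rotational_diffusion(self):
        vs = gen_rotdiff_vectors(RotDiffSpec(tau_c=5e-9, dt=50e-12, n_frames=100_000, seed=2))
        corr = p2_autocorrelation(vs, n_chunks=20, max_lag_fraction=0.5)
        mask = (corr.lags > 0) & (corr.lags <= 10e-9)
        expected = np.exp(-corr.lags[mask] / 5e-9)
        assert np.all(np.abs(corr.values[mask] - expected) <= 3 * corr.stderr[mask])

    def test_chunk_count_does_not_bias(self):
        vs = gen_rotdiff_vectors(RotDiffSpec(tau_c=1e-9, dt=20e-12, n_frames=60_000, seed=5))
        c10 = p2_autocorrelation(vs, n_chunks=10, max_lag_fraction=0.2)
        c20 = p2_autocorrelation(vs, n_chunks=20, max_lag_fraction=0.4)
        m = min(c10.values.size, c20.values.size)
        se = np.sqrt(c10.stderr[1:m] ** 2 + c20.stderr[1:m] ** 2)
        assert np.all(np.abs(c10.values[1:m] - c20.values[1:m]) <= 3 * se)

    def test_too_few_frames_rejected(self):
        v = np.tile([0.0, 0.0, 1.0], (10, 1))
        with pytest.raises(ValueError):
            p2_autocorrelation(VectorSeries(1, v, 1e-12), n_chunks=20)


class TestTriExponentialFit:
    def _corr(self, t, y):
        return CorrelationFunction(t, y, np.full(t.size, np.nan), 1)

    def test_single_exponential_recovered(self):
        t = np.linspace(0, 10e-9, 200)
        fit = fit_triexponential(self._corr(t, np.exp(-t / 2e-9)))
        assert fit.amplitudes.size == 1
        assert fit.amplitudes[0] == pytest.approx(1.0, abs=0.01)
        assert fit.taus[0] == pytest.approx(2e-9, rel=0.02)

    def test_double_exponential_recovered(self):
        t = np.linspace(0, 60e-9, 2000)
        y = 0.6 * np.exp(-t / 1e-9) + 0.4 * np.exp(-t / 20e-9)
        fit = fit_triexponential(self._corr(t, y))
        assert fit.amplitudes.size == 2
        assert fit.amplitudes[0] == pytest.approx(0.6, rel=0.05)
        assert fit.taus[0] == pytest.approx(1e-9, rel=0.05)
        assert fit.amplitudes[1] == pytest.approx(0.4, rel=0.05)
        assert fit.taus[1] == pytest.approx(20e-9, rel=0.05)

    def test_constant_input_becomes_plateau(self):
        t = np.linspace(0, 10e-9, 100)
        fit = fit_triexponential(self._corr(t, np.full(t.size, 0.8)))
        assert fit.amplitudes.size == 1
        assert fit.amplitudes[0] == pytest.approx(0.8, abs=0.01)
        assert fit.taus[0] >= 100 * t[-1]

    def test_too_few_points_rejected(self):
        t = np.linspace(0, 1e-9, 5)
        with pytest.raises(ValueError):
            fit_triexponential(self._corr(t, np.exp(-t / 1e-9)))


class TestApplyTumbling:
    def test_hand_evaluated_j0(self):
        from taildyn.relaxometry import TriExpFit

        fit = TriExpFit(np.array([0.5, 0.5]), np.array([1e-9, 1e9]), 0.0)
        sd = apply_tumbling(fit, 10e-9)
        # tau_eff = {1/(1/1+1/10) ns, ~10 ns}: J(0) = 0.4*(0.5*0.9091 + 0.5*10) ns
        assert sd.J(0.0) == pytest.approx(0.4 * (0.5 * (1 / 1.1) + 0.5 * 10.0) * 1e-9, rel=1e-6)

    def test_plateau_with_tumbling_is_rigid_rotor(self):
        from taildyn.relaxometry import TriExpFit

        fit = TriExpFit(np.array([1.0]), np.array([1e12]), 0.0)
        sd = apply_tumbling(fit, 163.4e-9)
        rigid = SpectralDensityModel.rigid_rotor(163.4e-9)
        for w in (0.0, 1e8, 3.8e9):
            assert sd.J(w) == pytest.approx(rigid.J(w), rel=1e-9)

    def test_infinite_tau_rot_keeps_internal_times(self):
        from taildyn.relaxometry import TriExpFit

        fit = TriExpFit(np.array([0.7, 0.3]), np.array([1e-9, 5e-9]), 0.0)
        sd = apply_tumbling(fit, math.inf)
        assert np.allclose(sd.tau_eff, [1e-9, 5e-9])


class TestRelaxationRates:
    def test_zero_spectral_density(self):
        sd = SpectralDensityModel(np.array([0.0]), np.array([1e-9]), 1e-9)
        rec = relaxation_rates(sd)
        assert rec.R1 == 0.0 and rec.R2 == 0.0
        assert not rec.noe_defined

    def test_rigid_rotor_matches_independent_oracle(self):
        tau = 163.4e-9
        rec = relaxation_rates(SpectralDensityModel.rigid_rotor(tau))
        R1, R2, noe = oracle_rates(lorentzian(tau))
        assert rec.R1 == pytest.approx(R1, rel=1e-9)
        assert rec.R2 == pytest.approx(R2, rel=1e-9)
        assert rec.NOE == pytest.approx(noe, rel=1e-9)

    def test_r2_monotone_in_tau_for_rigid_rotor(self):
        taus = np.linspace(1e-9, 300e-9, 60)
        r2 = [relaxation_rates(SpectralDensityModel.rigid_rotor(t)).R2 for t in taus]
        assert np.all(np.diff(r2) > 0)

    def test_r2_exceeds_r1_for_slow_tumbling(self):
        rec = relaxation_rates(SpectralDensityModel.rigid_rotor(163.4e-9))
        assert rec.R2 > rec.R1


class TestResidueTauC:
    def test_ratio_at_lower_edge_gives_zero(self):
        from taildyn.relaxometry import RelaxationRecord

        rec = RelaxationRecord(1, R1=6.0, R2=7.0, NOE=None)
        rec = residue_tau_c(rec)
        assert rec.tau_c_defined and rec.tau_c == 0.0

    def test_ratio_below_edge_flagged(self):
        from taildyn.relaxometry import RelaxationRecord

        rec = RelaxationRecord(1, R1=1.0, R2=1.0, NOE=None)
        rec = residue_tau_c(rec)
        assert not rec.tau_c_defined

    def test_eq2_identity_exact_without_high_frequency_terms(self):
        # with J(wH-wN), J(wH), J(wH+wN) zeroed the inversion is an
        # algebraic identity for any tau and any CSA
        for tau in np.geomspace(1e-9, 500e-9, 7):
            for csa in (-172.0, -80.0, 30.0):
                consts = SpinSystemConstants(csa_ppm=csa)
                rec = relaxation_rates(
                    SpectralDensityModel.rigid_rotor(tau), consts,
                    include_high_frequency=False,
                )
                rec = residue_tau_c(rec, consts)
                assert rec.tau_c == pytest.approx(tau, rel=1e-12)


class TestFullChain:
    def test_rotdiff_chain_reproduces_lorentzian_rates(self):
        tau_c = 5e-9
        vs = gen_rotdiff_vectors(RotDiffSpec(tau_c, 10e-12, 200_000, seed=1))
        corr = p2_autocorrelation(vs, n_chunks=20, max_lag_fraction=0.5)
        fit = fit_triexponential(corr)
        rec = relaxation_rates(apply_tumbling(fit, math.inf))
        ref = relaxation_rates(SpectralDensityModel.rigid_rotor(tau_c))
        assert rec.R1 == pytest.approx(ref.R1, rel=0.10)
        assert rec.R2 == pytest.approx(ref.R2, rel=0.10)

    def test_cone_with_tumbling_matches_model_free_rates(self):
        # Lipari-Szabo: J = 2/5 [S^2 tau_rot/(1+(w tau_rot)^2) + (1-S^2) tau'/(1+(w tau')^2)]
        half_angle, tau_int, tau_rot = 30.0, 1e-9, 20e-9
        vs = gen_cone_vectors(ConeSpec(half_angle, tau_int, 10e-12, 200_000, seed=3))
        corr = p2_autocorrelation(vs, n_chunks=20, max_lag_fraction=0.5)
        fit = fit_triexponential(corr)
        rec = relaxation_rates(apply_tumbling(fit, tau_rot))
        S2 = cone_order_parameter(half_angle) ** 2
        tau_p = 1.0 / (1.0 / tau_int + 1.0 / tau_rot)
        sd_mf = SpectralDensityModel(
            np.array([S2, 1 - S2]), np.array([tau_rot, tau_p]), tau_rot
        )
        ref = relaxation_rates(sd_mf)
        assert rec.R1 == pytest.approx(ref.R1, rel=0.15)
        assert rec.R2 == pytest.approx(ref.R2, rel=0.15)


class TestCompareToExperiment:
    def test_identical_inputs(self):
        vals = {1: 2.0, 2: 3.0, 3: 4.0, 7: 9.0}
        out = compare_to_experiment(vals, vals)
        assert out["r"] == pytest.approx(1.0)
        assert np.allclose(out["delta"], 0.0)

    def test_scale_invariance(self):
        a = {1: 2.0, 2: 3.0, 3: 5.0}
        b = {k: 2 * v for k, v in a.items()}
        assert compare_to_experiment(b, a)["r"] == pytest.approx(1.0)

    def test_hand_computed_four_points(self):
        x = {1: 1.0, 2: 2.0, 3: 3.0, 4: 4.0}
        y = {1: 2.0, 2: 1.0, 3: 4.0, 4: 3.0}
        # hand covariance: cov=0.75, sx^2=sy^2=1.25 -> r = 0.75/1.25 = 0.6
        assert compare_to_experiment(x, y)["r"] == pytest.approx(0.6)

    def test_too_few_shared_residues(self):
        with pytest.raises(ValueError, match="shared"):
            compare_to_experiment({1: 1.0, 2: 2.0}, {1: 1.0, 2: 2.0, 3: 3.0})
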