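"""Single-mass dynamics: sigmoid transfer, synaptic filters, closed loop."""

import math

import numpy as np
import pytest
from scipy.signal import welch

from vtrial.mass import (MassParams, MassState, impulse_response_step,
                         sigmoid_transfer, simulate_single_mass, step_mass)


class TestSigmoidTransfer:
    def test_midpoint_is_half_max(self):
        # S(Vd) = q / (1 + e^0) analytically
        assert sigmoid_transfer(7.0, 7.0, 5.0, 0.7) == pytest.approx(2.5)
        assert sigmoid_transfer(-3.0, -3.0, 11.0, 2.0) == pytest.approx(5.5)

    def test_saturation_limits(self):
        assert sigmoid_transfer(-1e3, 7.0, 5.0, 0.7) == pytest.approx(0.0, abs=1e-12)
        assert sigmoid_transfer(1e3, 7.0, 5.0, 0.7) == pytest.approx(5.0)

    def test_lower_threshold_raises_excitability(self):
        # lower threshold -> higher spike density at the same potential
        for vm in (-2.0, 5.0, 7.0, 12.0):
            assert sigmoid_transfer(vm, 5.0, 5.0, 0.7) > \
                sigmoid_transfer(vm, 7.0, 5.0, 0.7)

    def test_monotonicity_randomized(self):
        # strictly increasing in Vm, decreasing in Vd, bounded in (0, q):
        # checked over 1000 random parameter draws
        # arguments kept within the numerically representable sigmoid
        # range (|r * (Vm - Vd)| < 20); beyond that double precision
        # saturates the tails to exactly 0 or q
        rng = np.random.default_rng(0)
        for _ in range(1000):
            q = rng.uniform(0.5, 50)
            r = rng.uniform(0.05, 1.5)
            vd = rng.uniform(-6, 6)
            vm = rng.uniform(-6, 6)
            dv = rng.uniform(0.01, 1.0)
            s = sigmoid_transfer(vm, vd, q, r)
            assert 0 < s < q
            assert sigmoid_transfer(vm + dv, vd, q, r) > s
            assert sigmoid_transfer(vm, vd + dv, q, r) < s

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError, match="non-finite"):
            sigmoid_transfer(float("nan"), 7.0, 5.0, 0.7)
        with pytest.raises(ValueError, match="non-finite"):
            sigmoid_transfer(1.0, float("inf"), 5.0, 0.7)


class TestImpulseResponse:
    def test_dc_gain(self):
        # constant unit drive converges to the filter's DC gain A/a, B/b
        p = MassParams()
        st = MassState()
        for _ in range(4000):
            st = impulse_response_step(st, 1.0, 1.0, p, 1e-3)
        assert st.Ve == pytest.approx(p.A / p.a, rel=0.01)
        assert st.Vi == pytest.approx(p.B / p.b, rel=0.01)

    def test_zero_drive_zero_state(self):
        p = MassParams()
        st = MassState()
        for _ in range(100):
            st = impulse_response_step(st, 0.0, 0.0, p, 1e-3)
        assert st.Ve == 0.0 and st.Vi == 0.0 and st.z_e == 0.0

    def test_impulse_peaks_at_inverse_rate(self):
        # unit-area impulse response A*a*t*exp(-a*t): max A/e at t = 1/a
        p = MassParams()
        dt = 1e-5
        st = impulse_response_step(MassState(), 1.0 / dt, 0.0, p, dt)
        traj = []
        for _ in range(int(0.05 / dt)):
            st = impulse_response_step(st, 0.0, 0.0, p, dt)
            traj.append(st.Ve)
        traj = np.array(traj)
        t_peak = (np.argmax(traj) + 2) * dt
        assert t_peak == pytest.approx(1.0 / p.a, rel=0.02)
        assert traj.max() == pytest.approx(p.A / math.e, rel=0.01)

    def test_matches_high_resolution_reference(self):
        # dt = 1 ms trajectory vs a dt/100 reference under the same
        # sinusoidal drive: within 0.5 % relative error over 1 s
        p = MassParams()
        dt = 1e-3

        def drive_at(t):
            # drive held constant over each coarse step, so both
            # resolutions integrate the same input signal
            k = math.floor(t / dt + 1e-12)
            return 100.0 * (1.0 + math.sin(2 * math.pi * 5.0 * k * dt))

        def run(dt_):
            st = MassState()
            n = int(round(1.0 / dt_))
            out = np.empty(n)
            for i in range(n):
                st = impulse_response_step(st, drive_at(i * dt_), 0.0, p, dt_)
                out[i] = st.Ve
            return out

        coarse = run(dt)
        fine = run(dt / 100)[99::100]
        scale = np.abs(fine).max()
        assert np.max(np.abs(coarse - fine)) / scale < 0.005

    def test_unstable_dt_aborts_with_diagnostic(self):
        p = MassParams()
        st = MassState(Ve=1.0)
        with pytest.raises(FloatingPointError, match="dt"):
            for _ in range(500):
                st = impulse_response_step(st, 0.0, 0.0, p, 0.05)


class TestStepMass:
    def test_fixed_point_without_noise_or_input(self):
        # P = 0 and zero initial potentials: the loop settles to a
        # constant trajectory (a fixed point), no oscillation
        p = MassParams(P_mean=0.0, P_sd=0.0)
        st = MassState.resting(p)
        vals = []
        for _ in range(6000):
            st = step_mass(st, 0.0, p, 1e-3, 0.0)
            vals.append(st.Ve)
        tail = np.array(vals[-1000:])
        assert tail.std() < 1e-9

    def test_pulse_densities_bounded(self):
        p = MassParams()
        st = MassState.resting(p)
        rng = np.random.default_rng(4)
        for _ in range(2000):
            st = step_mass(st, rng.uniform(0, 50), p, 1e-3,
                           rng.normal(p.P_mean, p.P_sd))
            assert 0.0 <= st.E <= p.q and 0.0 <= st.I <= p.q

    def test_deterministic_given_same_draws(self):
        p = MassParams()

        def run():
            rng = np.random.default_rng(9)
            st = MassState.resting(p)
            for _ in range(500):
                st = step_mass(st, 0.0, p, 1e-3, rng.normal(p.P_mean, p.P_sd))
            return st

        a, b = run(), run()
        assert a == b

    def test_alpha_band_resonance(self):
        # the mass resonates in the alpha range: at its working input
        # level (coupled-network drive) the dominant peak is 8-13 Hz,
        # and even uncoupled the averaged spectrum peaks at the same
        # resonance (which sits at the lower edge of the band)
        p = MassParams()
        driven = MassParams(**{**p.__dict__, "P_mean": p.P_mean + 43.0})
        psds = []
        for seed in range(3):
            v = simulate_single_mass(driven, 8.0, 1e-3, seed)
            f, pxx = welch(v, fs=1000, nperseg=1000, noverlap=500,
                           nfft=4000, detrend="constant")
            psds.append(pxx)
        pxx = np.mean(psds, axis=0)
        sel = (f >= 1) & (f <= 30)
        peak = f[sel][np.argmax(pxx[sel])]
        assert 8.0 <= peak <= 13.0
        # uncoupled default: resonance bump present above the slow shelf
        psds = []
        for seed in range(3):
            v = simulate_single_mass(p, 8.0, 1e-3, seed)
            f, pxx = welch(v, fs=1000, nperseg=1000, noverlap=500,
                           nfft=4000, detrend="constant")
            psds.append(pxx)
        pxx = np.mean(psds, axis=0)
        sel = (f >= 5) & (f <= 30)
        bump = f[sel][np.argmax(pxx[sel])]
        assert 6.5 <= bump <= 11.0


def test_params_validation():
    with pytest.raises(ValueError):
        MassParams(A=-1.0)
    with pytest.raises(ValueError):
        MassParams(q=0.0)
    with pytest.raises(ValueError):
        MassParams(P_sd=-2.0)
    p = MassParams().with_thresholds(5.0, 6.5)
    assert (p.Vd1, p.Vd2) == (5.0, 6.5)
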