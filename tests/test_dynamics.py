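"""Core oscillator dynamics: limit cycle, coupling schemes, integration."""

import numpy as np
import pytest

from donn import (
    InputError,
    DivergenceError,
    LateralCoupling,
    OscillatorBank,
    all_to_all_coupling,
    coupling_drive,
    limit_cycle_amplitude,
    normalized_phase_differences,
    random_bank,
    simulate,
    step,
)
from donn.dynamics import OMEGA_MIN, R_FLOOR


def scalar_coupling_oracle(bank, coupling):
    """Non-vectorized re-evaluation of the printed coupling sums."""
    n = bank.n
    dr = np.zeros(n)
    dth = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if not coupling.mask[i, j]:
                continue
            g = coupling.xi_w * coupling.A[i, j]
            wi, wj = bank.omega[i], bank.omega[j]
            ri = max(bank.r[i], R_FLOOR)
            if coupling.scheme == "power":
                pw = bank.r[j] ** (wi / wj)
                arg = wi * (
                    bank.theta[j] / wj - bank.theta[i] / wi
                    + coupling.phi[i, j] / (wi * wj)
                )
                dr[i] += g * pw * np.cos(arg)
                dth[i] += g * pw * np.sin(arg) / ri
            elif coupling.scheme == "complex":
                arg = bank.theta[j] + coupling.phi[i, j] - bank.theta[i]
                dr[i] += g * bank.r[j] * np.cos(arg)
                dth[i] += g * bank.r[j] * np.sin(arg) / ri
            else:
                x_i = bank.r[i] * np.cos(bank.theta[i])
                x_j = bank.r[j] * np.cos(bank.theta[j])
                c = g * (x_j - x_i)
                dr[i] += c * np.cos(bank.theta[i])
                dth[i] += -c * np.sin(bank.theta[i]) / ri
    return dr, dth


@pytest.mark.parametrize(
    "mu, beta, expected",
    [(1.0, -20.0, np.sqrt(0.05)), (1.0, -1.0, 1.0), (0.5, -2.0, 0.5)],
)
def test_limit_cycle_amplitude(mu, beta, expected):
    assert limit_cycle_amplitude(mu, beta) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("mu, beta", [(1.0, 1.0), (-1.0, -1.0), (0.0, -1.0)])
def test_limit_cycle_amplitude_domain(mu, beta):
    with pytest.raises(InputError):
        limit_cycle_amplitude(mu, beta)


def test_coupling_drive_empty_mask():
    bank = random_bank(4, seed=0)
    coupling = LateralCoupling(
        np.zeros((4, 4)), np.zeros((4, 4)), np.zeros((4, 4), bool)
    )
    dr, dth = coupling_drive(bank, coupling)
    assert not dr.any() and not dth.any()
    dr, dth = coupling_drive(bank, None)
    assert not dr.any() and not dth.any()


def test_power_coupling_reduces_to_kuramoto_for_equal_frequencies():
    """With omega_i = omega_j and zero angles the power-coupled phase drive
    collapses to the classical (A r_j / r_i) sin(theta_j - theta_i) form."""
    omega = 2 * np.pi * 4.0
    bank = OscillatorBank(np.full(2, omega), np.array([0.3, 0.3]),
                          np.array([0.4, 1.7]))
    coupling = all_to_all_coupling(2, A0=0.05)
    _, dth = coupling_drive(bank, coupling)
    expected01 = 0.05 * (0.3 ** 1.0) / 0.3 * np.sin(bank.theta[1] - bank.theta[0])
    assert dth[0] == pytest.approx(expected01, rel=1e-12)
    assert dth[1] == pytest.approx(-expected01, rel=1e-12)


@pytest.mark.parametrize("scheme", ["power", "complex", "linear_all", "linear_nn"])
@pytest.mark.parametrize("n", [2, 5])
def test_coupling_drive_matches_scalar_oracle(scheme, n, rng):
    bank = OscillatorBank(
        rng.uniform(2 * np.pi * 1, 2 * np.pi * 9, n),
        rng.uniform(0.05, 1.0, n),
        rng.uniform(-10, 10, n),
    )
    mask = (
        np.abs(np.subtract.outer(np.arange(n), np.arange(n))) == 1
        if scheme == "linear_nn"
        else rng.random((n, n)) < 0.7
    )
    np.fill_diagonal(mask, False)
    coupling = LateralCoupling(
        np.where(mask, rng.uniform(0, 0.1, (n, n)), 0.0),
        rng.uniform(0, 2 * np.pi, (n, n)),
        mask, scheme, xi_w=0.7,
    )
    dr, dth = coupling_drive(bank, coupling)
    dr_o, dth_o = scalar_coupling_oracle(bank, coupling)
    np.testing.assert_allclose(dr, dr_o, rtol=1e-12, atol=1e-14)
    np.testing.assert_allclose(dth, dth_o, rtol=1e-12, atol=1e-14)


def test_uncoupled_amplitude_converges_to_limit_cycle():
    for r0 in (0.05, 0.5, 2.0):
        bank = OscillatorBank(np.array([2 * np.pi * 5]), np.array([r0]),
                              np.array([0.0]))
        final = simulate(bank, None, duration=10.0, dt=0.002)
        assert abs(final.r[0] - np.sqrt(0.05)) < 1e-3


def test_uncoupled_phase_grows_linearly():
    omega = 2 * np.pi * 3.0
    bank = OscillatorBank(np.array([omega]), np.array([np.sqrt(0.05)]),
                          np.array([1.0]))
    final = simulate(bank, None, duration=2.0, dt=0.002)
    assert final.theta[0] - 1.0 == pytest.approx(omega * 2.0, rel=1e-9)


def test_identical_pair_power_coupling_locks_in_phase():
    omega = 2 * np.pi * 4.0
    bank = OscillatorBank(np.full(2, omega), np.full(2, np.sqrt(0.05)),
                          np.array([0.0, 2.5]))
    coupling = all_to_all_coupling(2, A0=0.05)

    def wrapped_diff(state):
        d = (state.theta[0] - state.theta[1]) % (2 * np.pi)
        return min(d, 2 * np.pi - d)

    mid = simulate(bank, coupling, duration=10.0, dt=0.002)
    final = simulate(mid, coupling, duration=10.0, dt=0.002)
    assert wrapped_diff(mid) < 2.5
    assert wrapped_diff(final) < wrapped_diff(mid)
    assert wrapped_diff(final) < 1.0


@pytest.mark.parametrize("f1, f2", [(3.0, 7.0), (2.3, 6.1), (4.0, 9.0)])
def test_power_coupling_constant_normalized_phase_difference(f1, f2):
    """A power-coupled pair of unequal frequencies settles to a constant
    normalized phase difference theta/omega (the defining property)."""
    omega = 2 * np.pi * np.array([f1, f2])
    bank = OscillatorBank(omega, np.full(2, np.sqrt(0.05)), np.array([0.0, 1.0]))
    coupling = all_to_all_coupling(2, A0=0.05)
    cur = bank
    n_trans = int(10.0 / 0.002)
    n_meas = int(5.0 / 0.002)
    for _ in range(n_trans):
        cur = step(cur, coupling, dt=0.002)
    vals = np.empty(n_meas)
    for k in range(n_meas):
        cur = step(cur, coupling, dt=0.002)
        vals[k] = normalized_phase_differences(cur)[0, 1]
    assert np.std(vals) < 1e-2


def test_rk4_halving_dt_shrinks_error_by_at_least_4x():
    omega = 2 * np.pi * np.array([3.0, 7.0])
    bank = OscillatorBank(omega, np.array([0.4, 0.1]), np.array([0.0, 1.0]))
    coupling = all_to_all_coupling(2, A0=0.05)
    ref = simulate(bank, coupling, duration=2.0, dt=1e-4)

    def err(dt):
        fin = simulate(bank, coupling, duration=2.0, dt=dt)
        return np.max(np.abs(np.concatenate([fin.r - ref.r, fin.theta - ref.theta])))

    e1, e2 = err(0.008), err(0.004)
    assert e2 < e1 / 4.0


def test_step_euler_matches_hand_computed_update():
    bank = OscillatorBank(np.array([2 * np.pi * 2]), np.array([0.3]),
                          np.array([0.5]))
    e, eps, dt = 0.7, 1.3, 0.002
    new = step(bank, None, error_drive=e, epsilon=eps, dt=dt, integrator="euler")
    dr = (1.0 - 20.0 * 0.09) * 0.3 + eps * e * np.cos(0.5)
    dth = bank.omega[0] - eps * e * np.sin(0.5) / 0.3
    assert new.r[0] == pytest.approx(0.3 + dt * dr, rel=1e-12)
    assert new.theta[0] == pytest.approx(0.5 + dt * dth, rel=1e-12)


def test_step_rejects_bad_arguments():
    bank = random_bank(2, seed=0)
    with pytest.raises(InputError):
        step(bank, dt=0.0)
    with pytest.raises(InputError):
        step(bank, epsilon=-1.0, dt=0.002)
    with pytest.raises(InputError):
        step(bank, dt=0.002, integrator="leapfrog")


def test_step_reports_divergence_with_oscillator_index():
    # mu > 0, beta > 0: amplitude grows without bound and overflows
    bank = OscillatorBank(np.array([2 * np.pi]), np.array([2.0]),
                          np.array([0.0]), mu=1.0, beta=50.0)
    with pytest.raises(DivergenceError), np.errstate(all="ignore"):
        for _ in range(400):
            bank = step(bank, None, dt=0.05, integrator="euler")


def test_normalized_phase_differences_properties(rng):
    bank = OscillatorBank(np.zeros(3) + 2 * np.pi, np.ones(3), np.zeros(3))
    assert not normalized_phase_differences(bank).any()
    # common normalized phase theta_i = omega_i * c
    omega = rng.uniform(1, 50, 4)
    bank = OscillatorBank(omega, np.ones(4), omega * 0.37)
    np.testing.assert_allclose(normalized_phase_differences(bank), 0.0, atol=1e-14)
    # arbitrary state equals the pairwise scalar recomputation; antisymmetric
    bank = OscillatorBank(omega, np.ones(4), rng.uniform(-9, 9, 4))
    mat = normalized_phase_differences(bank)
    for i in range(4):
        for j in range(4):
            expected = bank.theta[i] / omega[i] - bank.theta[j] / omega[j]
            assert mat[i, j] == pytest.approx(expected, abs=1e-14)
    np.testing.assert_allclose(mat, -mat.T, atol=1e-14)


def test_bank_validation():
    with pytest.raises(InputError):
        OscillatorBank(np.array([1.0]), np.array([-0.1]), np.array([0.0]))
    with pytest.raises(InputError):
        OscillatorBank(np.array([0.01]), np.array([0.1]), np.array([0.0]))
    with pytest.raises(InputError):
        OscillatorBank(np.array([1.0, 2.0]), np.array([0.1]), np.array([0.0]))
    bank = OscillatorBank(np.array([2 * np.pi]), np.array([0.5]), np.array([np.pi]))
    assert bank.z[0] == pytest.approx(0.5 * np.exp(1j * np.pi))


def test_coupling_validation():
    mask = np.ones((3, 3), bool)
    c = LateralCoupling(np.full((3, 3), 0.1), np.zeros((3, 3)), mask)
    assert not c.mask.diagonal().any()
    assert (c.A.diagonal() == 0).all()
    with pytest.raises(InputError):
        LateralCoupling(np.zeros((3, 3)), np.zeros((3, 3)), mask[:2])
    with pytest.raises(InputError):
        LateralCoupling(np.zeros((3, 3)), np.zeros((3, 3)), mask, scheme="foo")
    nn = all_to_all_coupling(4, scheme="linear_nn")
    expected = np.abs(np.subtract.outer(np.arange(4), np.arange(4))) == 1
    assert (nn.mask == expected).all()


def test_random_bank_seeded_and_floored():
    b1 = random_bank(10, seed=3, omega_range_hz=(0.0, 10.0))
    b2 = random_bank(10, seed=3, omega_range_hz=(0.0, 10.0))
    assert np.array_equal(b1.omega, b2.omega)
    assert np.array_equal(b1.theta, b2.theta)
    assert (b1.omega >= OMEGA_MIN).all()
    assert (b1.r >= 0.1).all() and (b1.r <= 1.0).all()
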