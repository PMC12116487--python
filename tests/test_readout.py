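"""Stage-2 readouts: forward passes, gradients, training, harmonic gain."""

import numpy as np
import pytest

from donn import (
    ComplexLinearReadout,
    DivergenceError,
    HiddenReadout,
    harmonic_enrichment_demo,
    hidden_forward,
    init_hidden_readout,
    init_linear_readout,
    linear_forward,
    train_hidden,
    train_linear,
)
from donn.readout import hidden_loss_grads, linear_loss_grads


def ideal_phases(freqs_hz, n_t=1000, fs=500.0):
    t = np.arange(n_t) / fs
    return 2 * np.pi * np.asarray(freqs_hz)[None, :] * t[:, None]


# ---------------------------------------------------------------- linear


def test_linear_forward_examples(rng):
    ro = ComplexLinearReadout(np.zeros((2, 3)), np.zeros((2, 3)))
    assert not linear_forward(ro, rng.uniform(0, 9, 3)).any()
    ro1 = ComplexLinearReadout(np.array([[1.0]]), np.array([[0.0]]))
    assert linear_forward(ro1, np.array([0.0]))[0] == pytest.approx(1.0)


def test_linear_forward_matches_complex_arithmetic_oracle(rng):
    n_ch, n_o, n_t = 3, 5, 40
    ro = ComplexLinearReadout(rng.uniform(0, 1, (n_ch, n_o)),
                              rng.uniform(0, 2 * np.pi, (n_ch, n_o)))
    th = rng.uniform(-20, 20, (n_t, n_o))
    got = linear_forward(ro, th)
    w = ro.K * np.exp(1j * ro.xi)
    expected = np.real(np.exp(1j * th) @ w.T)
    np.testing.assert_allclose(got, expected, rtol=1e-12, atol=1e-12)


def test_negative_magnitudes_fold_into_angle():
    ro = ComplexLinearReadout(np.array([[-0.5]]), np.array([[0.3]]))
    assert ro.K[0, 0] == 0.5
    th = np.array([[1.1]])
    assert linear_forward(ro, th)[0, 0] == pytest.approx(
        -0.5 * np.cos(1.1 + 0.3)
    )


def test_linear_gradients_match_central_differences(rng):
    th = rng.uniform(-5, 5, (30, 3))
    target = rng.standard_normal((30, 2))
    ro = ComplexLinearReadout(rng.uniform(0.1, 1, (2, 3)),
                              rng.uniform(0, 2 * np.pi, (2, 3)))
    loss, dK, dxi = linear_loss_grads(ro, th, target)
    h = 1e-6
    for (i, j) in [(0, 0), (1, 2), (0, 1)]:
        for arr, grad in ((ro.K, dK), (ro.xi, dxi)):
            orig = arr[i, j]
            arr[i, j] = orig + h
            lp = linear_loss_grads(ro, th, target)[0]
            arr[i, j] = orig - h
            lm = linear_loss_grads(ro, th, target)[0]
            arr[i, j] = orig
            assert grad[i, j] == pytest.approx((lp - lm) / (2 * h), rel=1e-5)


def test_train_linear_single_epoch_matches_hand_computed_update():
    th = np.array([[0.2], [1.1], [2.9]])
    target = np.array([[0.5], [-0.3], [0.8]])
    ro = ComplexLinearReadout(np.array([[0.4]]), np.array([[0.7]]),
                              eta_K=1e-3, eta_xi=1e-4)
    out = train_linear(ro, th, target, epochs=1)
    err = target[:, 0] - 0.4 * np.cos(th[:, 0] + 0.7)
    dK = np.sum(err * np.cos(th[:, 0] + 0.7))
    dxi = 0.4 * np.sum(err * np.sin(th[:, 0] + 0.7))
    assert out.K[0, 0] == pytest.approx(0.4 + 1e-3 * dK, rel=1e-12)
    assert out.xi[0, 0] == pytest.approx(0.7 - 1e-4 * dxi, rel=1e-12)


def test_train_linear_recovers_known_readout(rng):
    """Self-consistency: a target generated by a readout of the same family
    is re-fit essentially exactly."""
    th = ideal_phases([2.0, 5.0, 8.0, 11.0], n_t=2000)
    true = ComplexLinearReadout(rng.uniform(0.3, 1.0, (1, 4)),
                                rng.uniform(0, 2 * np.pi, (1, 4)))
    target = linear_forward(true, th)
    ro = init_linear_readout(1, 4, seed=3, eta_K=1e-4, eta_xi=1e-4, epochs=20000)
    ro = train_linear(ro, th, target)
    res = target - linear_forward(ro, th)
    assert np.sum(res**2) < 1e-6 * np.sum(target**2)


def test_train_linear_dc_target_leaves_weights_near_zero():
    """Zero-mean cosines cannot represent DC: with phases sweeping whole
    cycles the K-gradient vanishes."""
    th = ideal_phases([2.0, 4.0], n_t=500)  # integer cycles over the window
    target = np.full((500, 1), 0.7)
    ro = ComplexLinearReadout(np.zeros((1, 2)), np.zeros((1, 2)),
                              eta_K=1e-4, eta_xi=1e-6)
    out = train_linear(ro, th, target, epochs=50)
    assert np.all(out.K < 1e-10)


def test_train_linear_divergence_guard():
    th = ideal_phases([3.0], n_t=400)
    target = np.sin(th[:, :1] * 1.0)
    ro = ComplexLinearReadout(np.array([[0.1]]), np.array([[0.0]]), eta_K=0.5)
    with pytest.raises(DivergenceError):
        train_linear(ro, th, target, epochs=200)


# ---------------------------------------------------------------- hidden


def test_hidden_forward_zero_weights_identity_output():
    ro = HiddenReadout(np.zeros((4, 3), complex), np.zeros(4), np.zeros((1, 4)),
                       np.zeros(1), output_activation="identity")
    assert not hidden_forward(ro, np.zeros(3)).any()


def test_hidden_forward_small_weight_linear_regime():
    """With tiny first-layer weights tanh is linear, so the hidden readout
    reduces to a scaled cosine of (theta + xi)."""
    eps = 1e-4
    w = eps * np.exp(1j * 0.6)
    ro = HiddenReadout(np.array([[w]]), np.zeros(1), np.array([[1.0]]),
                       np.zeros(1), output_activation="identity")
    th = np.linspace(0, 2 * np.pi, 40)[:, None]
    got = hidden_forward(ro, th)[:, 0]
    # Re(w e^{i theta}) = eps * cos(theta + 0.6)
    expected = eps * np.cos(th[:, 0] + 0.6)
    np.testing.assert_allclose(got, expected, rtol=1e-6)


def test_hidden_forward_matches_scalar_oracle(rng):
    n_t, n_o, n_h, n_c = 7, 3, 4, 2
    ro = init_hidden_readout(n_c, n_o, n_h, seed=2)
    ro.output_scale = np.array([1.3, 0.8])
    th = rng.uniform(-9, 9, (n_t, n_o))
    got = hidden_forward(ro, th)
    for t in range(n_t):
        h = np.empty(n_h)
        for k in range(n_h):
            acc = ro.b_h[k]
            for j in range(n_o):
                acc += (ro.W_in[k, j].real * np.cos(th[t, j])
                        - ro.W_in[k, j].imag * np.sin(th[t, j]))
            h[k] = np.tanh(acc)
        for c in range(n_c):
            y = np.tanh(ro.W_out[c] @ h + ro.b_o[c]) * ro.output_scale[c]
            assert got[t, c] == pytest.approx(y, rel=1e-12)


@pytest.mark.parametrize("activation", ["tanh", "identity"])
@pytest.mark.parametrize("complex_input", [True, False])
def test_hidden_gradients_match_central_differences(activation, complex_input, rng):
    ro = init_hidden_readout(1, 3, 2, seed=4, output_activation=activation,
                             complex_input=complex_input)
    ro.output_scale = np.array([1.7])
    th = rng.uniform(-5, 5, (20, 3))
    target = rng.standard_normal((20, 1))
    _, grads = hidden_loss_grads(ro, th, target)
    h = 1e-6

    def loss():
        return hidden_loss_grads(ro, th, target)[0]

    def check(get, set_, g):
        orig = get()
        set_(orig + h)
        lp = loss()
        set_(orig - h)
        lm = loss()
        set_(orig)
        fd = (lp - lm) / (2 * h)
        assert g == pytest.approx(fd, rel=1e-5, abs=1e-12)

    check(lambda: ro.W_in[0, 1].real,
          lambda v: ro.W_in.__setitem__((0, 1), v + 1j * ro.W_in[0, 1].imag),
          grads["a"][0, 1])
    if complex_input:
        check(lambda: ro.W_in[1, 2].imag,
              lambda v: ro.W_in.__setitem__((1, 2), ro.W_in[1, 2].real + 1j * v),
              grads["b"][1, 2])
    check(lambda: ro.b_h[0],
          lambda v: ro.b_h.__setitem__(0, v), grads["b_h"][0])
    check(lambda: ro.W_out[0, 1],
          lambda v: ro.W_out.__setitem__((0, 1), v), grads["W_out"][0, 1])
    check(lambda: ro.b_o[0],
          lambda v: ro.b_o.__setitem__(0, v), grads["b_o"][0])


def test_train_hidden_recovers_same_family_target():
    th = ideal_phases([3.0, 7.0], n_t=1000)
    true = init_hidden_readout(1, 2, 4, seed=11)
    true.W_in = true.W_in * 4
    true.W_out = true.W_out * 4
    target = hidden_forward(true, th)
    fit = init_hidden_readout(1, 2, 32, seed=5, eta_h=0.01, eta_o=0.01,
                              epochs=12000, optimizer="adam")
    fit = train_hidden(fit, th, target)
    res = target - hidden_forward(fit, th)
    assert np.mean(res**2) < 1e-5 * np.mean(target**2)


def test_train_hidden_zero_target_decays_output():
    th = ideal_phases([3.0], n_t=400)
    ro = init_hidden_readout(1, 1, 6, seed=8, output_activation="identity",
                             eta_h=0.05, eta_o=0.05)
    before = np.sqrt(np.mean(hidden_forward(ro, th) ** 2))
    out = train_hidden(ro, th, np.zeros((400, 1)), epochs=500, set_scale=False)
    after = np.sqrt(np.mean(hidden_forward(out, th) ** 2))
    assert after < 0.1 * before


def test_train_hidden_divergence_guard():
    th = ideal_phases([3.0], n_t=200)
    target = np.sin(th[:, :1])
    ro = init_hidden_readout(1, 1, 4, seed=0, eta_h=500.0, eta_o=500.0,
                             output_activation="identity")
    with pytest.raises(DivergenceError), np.errstate(all="ignore"):
        train_hidden(ro, th, target, epochs=300)


# ------------------------------------------------- harmonic enrichment


def test_harmonic_enrichment_hidden_beats_linear():
    """With oscillators at 2/6/10 Hz only, the 14 Hz harmonic is out of
    reach for the linear readout; tanh inter-modulation recovers it."""
    rmse_lin, rmse_hid = harmonic_enrichment_demo(seed=0)
    assert rmse_hid < 0.5 * rmse_lin


def test_harmonic_enrichment_no_advantage_when_linear_suffices():
    t = np.arange(2000) / 500.0
    teacher = np.sin(2 * np.pi * 2.0 * t)
    rmse_lin, rmse_hid = harmonic_enrichment_demo(
        teacher=teacher, seconds=4.0, osc_freqs_hz=np.array([2.0]),
        hidden_epochs=2000, seed=0,
    )
    rms = np.sqrt(np.mean(teacher**2))
    assert rmse_lin < 0.05 * rms
    assert rmse_hid < 0.15 * rms


def test_harmonic_enrichment_noise_is_unfittable(rng):
    teacher = rng.standard_normal(2000)
    rmse_lin, rmse_hid = harmonic_enrichment_demo(
        teacher=teacher, seconds=4.0, hidden_epochs=1000, seed=0,
    )
    rms = np.sqrt(np.mean(teacher**2))
    assert 0.8 * rms < rmse_lin < 1.2 * rms
    assert 0.8 * rms < rmse_hid < 1.2 * rms
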