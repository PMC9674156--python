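"""Encoder behaviour: recurrence base cases, brute-force convolution oracles,
shape/positivity contracts, and finite-difference gradient checks."""

import numpy as np
import pytest

from pclm.autodiff import Tensor, lstm_direction
from pclm.encoders import (EncoderParams, build_motif_kernels, encode_function,
                           encode_sequence, encode_structure)
from pclm.types import (AA_ORDER, ContactMap, MotifPWM, ProteinRecord,
                        SequenceProfile)
from conftest import finite_diff_grad, rel_err


def make_params(rng, motifs, h=4, c=2, k=3, d_stc=3):
    return EncoderParams.create(rng, motifs, h=h, c=c, k=k, d_stc=d_stc)


@pytest.fixture()
def enc_params(toy_motifs):
    return make_params(np.random.default_rng(2), toy_motifs)


# ------------------------------------------------------------------- sequence

def test_bilstm_length_one_matches_single_step(enc_params):
    """At L=1 each direction is one recurrence step from zero initial state."""
    X = np.random.default_rng(0).normal(size=(1, 40)) * 0.1
    X[:, 20:] = np.abs(X[:, 20:]) / 2
    prof = SequenceProfile("p", X)
    block = encode_sequence(prof, enc_params)
    h = enc_params.lstm_hidden

    def one_step(Wx, Wh, b, x):
        z = x @ Wx.data + b.data
        from scipy.special import expit
        i, f, o = expit(z[:h]), expit(z[h:2 * h]), expit(z[2 * h:3 * h])
        g = np.tanh(z[3 * h:])
        c = i * g
        return o * np.tanh(c)

    x = prof.X[0]
    expected = np.concatenate([
        one_step(enc_params.Wx_f, enc_params.Wh_f, enc_params.b_f, x),
        one_step(enc_params.Wx_b, enc_params.Wh_b, enc_params.b_b, x)])
    assert np.allclose(block.V.data[0], expected, atol=1e-12)


def test_bilstm_reversal_symmetry(toy_motifs):
    """With shared forward/backward weights, reversing the input reverses the
    output rows and swaps the direction halves."""
    rng = np.random.default_rng(3)
    params = make_params(rng, toy_motifs)
    params.Wx_b = Tensor(params.Wx_f.data.copy(), True)
    params.Wh_b = Tensor(params.Wh_f.data.copy(), True)
    params.b_b = Tensor(params.b_f.data.copy(), True)
    X = rng.normal(size=(7, 40)) * 0.3
    X[:, 20:] = np.abs(X[:, 20:]) / 10
    out = encode_sequence(SequenceProfile("p", X), params).V.data
    out_rev = encode_sequence(SequenceProfile("p", X[::-1]), params).V.data
    h = params.lstm_hidden
    swapped = np.concatenate([out_rev[:, h:], out_rev[:, :h]], axis=1)
    assert np.allclose(swapped, out[::-1], atol=1e-12)


def test_lstm_gradients_match_finite_differences(toy_motifs):
    """Backprop through the Bi-LSTM agrees with central differences."""
    rng = np.random.default_rng(4)
    params = make_params(rng, toy_motifs)
    X = rng.normal(size=(5, 40)) * 0.5
    X[:, 20:] = np.abs(X[:, 20:])
    X[:, 20:] /= X[:, 20:].max()
    w = rng.normal(size=(5, 2 * params.lstm_hidden))

    def loss_fn():
        block = encode_sequence(SequenceProfile("p", X), params)
        return float((block.V * Tensor(w)).sum().data)

    block = encode_sequence(SequenceProfile("p", X), params)
    loss = (block.V * Tensor(w)).sum()
    loss.backward()
    for name in ("Wx_f", "Wh_f", "b_f", "Wx_b", "Wh_b", "b_b"):
        t = getattr(params, name)
        num = finite_diff_grad(loss_fn, t.data)
        assert rel_err(num, t.grad) < 1e-6, name


# ------------------------------------------------------------------ structure

def naive_conv2d(Y, K):
    """Quadruple-loop same-padded 2D correlation oracle."""
    k = K.shape[0]
    pad = k // 2
    L = Y.shape[0]
    out = np.zeros((L, L))
    for i in range(L):
        for j in range(L):
            for u in range(k):
                for v in range(k):
                    ii, jj = i + u - pad, j + v - pad
                    if 0 <= ii < L and 0 <= jj < L:
                        out[i, j] += K[u, v] * Y[ii, jj]
    return out


def test_conv_bank_matches_naive_loops(enc_params):
    rng = np.random.default_rng(5)
    Y = np.abs(rng.normal(size=(7, 7)))
    Y = 0.5 * (Y + Y.T)
    out = Tensor(Y).conv2d_bank(enc_params.conv_kernels).data
    for f in range(enc_params.conv_kernels.data.shape[0]):
        assert np.allclose(out[:, :, f],
                           naive_conv2d(Y, enc_params.conv_kernels.data[f]),
                           atol=1e-12)


def test_zero_map_zero_bias_gives_zero_block(enc_params):
    enc_params.b_stc = Tensor(np.zeros_like(enc_params.b_stc.data), True)
    cm = ContactMap("p", np.zeros((6, 6)))
    block = encode_structure(cm, enc_params)
    assert np.allclose(block.V.data, 0.0)


def test_structure_block_nonnegative(enc_params, small_proteome):
    block = encode_structure(small_proteome.items[0].contacts, enc_params)
    assert block.V.data.min() >= 0.0


def test_structure_permutation_equivariance_1x1_kernels(toy_motifs):
    """With 1x1 kernels the conv+row-pool pipeline commutes with simultaneous
    row/column permutation of the contact map.  (For k>1 a 2D convolution is
    only translation-equivariant, so the general claim does not hold.)"""
    rng = np.random.default_rng(6)
    params = make_params(rng, toy_motifs, k=1)
    Y = np.abs(rng.normal(size=(9, 9)))
    Y = 0.5 * (Y + Y.T)
    perm = rng.permutation(9)
    out = encode_structure(ContactMap("p", Y), params).V.data
    out_p = encode_structure(ContactMap("p", Y[np.ix_(perm, perm)]), params).V.data
    assert np.allclose(out_p, out[perm], atol=1e-12)


def test_structure_rejects_short_map(enc_params):
    with pytest.raises(ValueError, match="shorter than kernel"):
        encode_structure(ContactMap("p", np.zeros((2, 2))), enc_params)


# ------------------------------------------------------------------- function

def test_build_motif_kernels_copies_verbatim(toy_motifs):
    kernels = build_motif_kernels(toy_motifs)
    for k, m in zip(kernels, toy_motifs):
        assert np.array_equal(k.data, m.M)
        assert not k.requires_grad  # frozen by default


def test_build_motif_kernels_164(tmp_path):
    rng = np.random.default_rng(7)
    motifs = [MotifPWM(f"m{i}", rng.dirichlet(np.ones(20), size=5))
              for i in range(164)]
    assert len(build_motif_kernels(motifs)) == 164


def test_build_motif_kernels_empty_bank_errors():
    with pytest.raises(ValueError, match="empty"):
        build_motif_kernels([])


def test_uniform_pwm_kernel_is_all_point_05():
    m = MotifPWM("u", np.full((1, 20), 0.05))
    assert np.allclose(build_motif_kernels([m])[0].data, 0.05)


def naive_motif_scan(seq, M, b):
    """Brute-force centred PWM scan with zero padding."""
    L = len(seq)
    lm = M.shape[0]
    off = lm // 2
    out = np.zeros(L)
    for i in range(L):
        s = b
        for j in range(lm):
            pos = i + j - off
            if 0 <= pos < L and seq[pos] != "X":
                s += M[j, AA_ORDER.index(seq[pos])]
        out[i] = max(s, 0.0)
    return out


def test_deterministic_pwm_peaks_on_its_consensus(toy_motifs):
    """A one-hot PWM scanned over a sequence containing its consensus exactly
    once attains its unique maximum (= l_m + b pre-relu) centred on it."""
    M = np.zeros((3, 20))
    for i, a in enumerate("KRD"):
        M[i, AA_ORDER.index(a)] = 1.0
    motif = MotifPWM("det", M)
    params = EncoderParams.create(np.random.default_rng(8), [motif])
    params.b_func = Tensor(np.array([0.25]), True)
    seq = "AAAKRDAAA"
    rec = ProteinRecord("p", seq)
    block = encode_function(rec.one_hot(), build_motif_kernels([motif]), params)
    col = block.V.data[:, 0]
    assert col.argmax() == 4  # centre of KRD at positions 3..5
    assert col.max() == pytest.approx(3 + 0.25)
    assert (col < col.max()).sum() == len(seq) - 1
    assert np.allclose(col, naive_motif_scan(seq, M, 0.25), atol=1e-12)


def test_motif_scan_matches_naive_oracle(toy_motifs, enc_params):
    rng = np.random.default_rng(9)
    seq = "".join(rng.choice(list(AA_ORDER + "X"), size=30))
    rec = ProteinRecord("p", seq)
    block = encode_function(rec.one_hot(), enc_params.motif_kernels, enc_params)
    for m, motif in enumerate(toy_motifs):
        expected = naive_motif_scan(seq, motif.M, enc_params.b_func.data[m])
        assert np.allclose(block.V.data[:, m], expected, atol=1e-12)


def test_all_x_sequence_zero_bias_gives_zero_func(toy_motifs, enc_params):
    enc_params.b_func = Tensor(np.zeros(2), True)
    rec = ProteinRecord("p", "XXXXXX")
    block = encode_function(rec.one_hot(), enc_params.motif_kernels, enc_params)
    assert np.allclose(block.V.data, 0.0)


@pytest.mark.parametrize("L", [5, 50, 500])
def test_function_block_shape(L, toy_motifs, enc_params):
    rng = np.random.default_rng(L)
    rec = ProteinRecord("p", "".join(rng.choice(list(AA_ORDER), size=L)))
    block = encode_function(rec.one_hot(), enc_params.motif_kernels, enc_params)
    assert block.V.data.shape == (L, len(toy_motifs))
    assert block.V.data.min() >= 0.0
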