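"""Alignment, cubic fusion and the propensity head: hand-computed softmax
cases, brute-force complement oracle, linearity of fusion, and the
end-to-end finite-difference gradient check."""

import numpy as np
import pytest

from pclm.autodiff import Tensor
from pclm.encoders import FeatureBlock
from pclm.fusion import (AlignmentParams, AttentionMap, FusionParams, align,
                         complement, export_attention, fuse,
                         predict_propensities, propensity_tensor,
                         read_attention)
from pclm.model import ModelConfig, PCLM
from pclm.train import _bce_tensor
from pclm.types import MotifPWM
from conftest import finite_diff_grad, rel_err


def blocks_of(rng, L, d_seq=4, d_stc=3, d_func=2):
    mk = lambda shape: rng.normal(size=shape)
    return (FeatureBlock("Seq", Tensor(mk((L, d_seq)))),
            FeatureBlock("Stc", Tensor(np.abs(mk((L, d_stc))))),
            FeatureBlock("Func", Tensor(np.abs(mk((L, d_func))))))


@pytest.fixture()
def align_params():
    rng = np.random.default_rng(1)
    return AlignmentParams.create(rng, {"Seq": 4, "Stc": 3, "Func": 2},
                                  d_a=3, d_c=3)


# ------------------------------------------------------------------ alignment

def test_constant_logits_give_uniform_attention(align_params):
    rng = np.random.default_rng(2)
    L = 6
    seq, stc, _ = blocks_of(rng, L)
    # zero first-stage projection of Stc forces constant (zero) logits
    align_params.H1["Stc"] = Tensor(np.zeros((3, 3)), True)
    amap = align(seq, stc, align_params)
    assert np.allclose(amap.alpha.data, 1.0 / L)


@pytest.mark.parametrize("L", [2, 17, 101])
def test_attention_rows_sum_to_one(L, align_params):
    rng = np.random.default_rng(L)
    seq, stc, _ = blocks_of(rng, L)
    amap = align(seq, stc, align_params)
    assert np.abs(amap.alpha.data.sum(axis=1) - 1.0).max() < 1e-6
    assert amap.alpha.data.min() > 0.0


def test_softmax_hand_case():
    """Logits [[0, ln3], [0, 0]] -> [[0.25, 0.75], [0.5, 0.5]]."""
    logits = Tensor(np.array([[0.0, np.log(3.0)], [0.0, 0.0]]))
    a = logits.row_softmax().data
    assert np.allclose(a, [[0.25, 0.75], [0.5, 0.5]], atol=1e-12)


def test_align_rejects_length_mismatch(align_params):
    rng = np.random.default_rng(3)
    seq, _, _ = blocks_of(rng, 4)
    _, stc, _ = blocks_of(rng, 5)
    with pytest.raises(ValueError, match="mismatch"):
        align(seq, stc, align_params)


# ----------------------------------------------------------------- complement

def test_identity_attention_complement(align_params):
    rng = np.random.default_rng(4)
    seq, stc, _ = blocks_of(rng, 5)
    amap = AttentionMap("seq-stc", Tensor(np.eye(5)))
    out = complement(amap, seq, stc, align_params).V.data
    expected = np.concatenate([seq.V.data @ align_params.H2["Seq"].data,
                               stc.V.data @ align_params.H2["Stc"].data], axis=1)
    assert np.allclose(out, expected, atol=1e-12)


def test_uniform_attention_averages_columns(align_params):
    rng = np.random.default_rng(5)
    L = 6
    seq, stc, _ = blocks_of(rng, L)
    amap = AttentionMap("seq-stc", Tensor(np.full((L, L), 1.0 / L)))
    out = complement(amap, seq, stc, align_params).V.data
    left = (seq.V.data.mean(axis=0) @ align_params.H2["Seq"].data)
    right = (stc.V.data.mean(axis=0) @ align_params.H2["Stc"].data)
    # alpha^T A with uniform alpha averages A's rows; alpha B likewise
    assert np.allclose(out[:, :3], np.tile(left, (L, 1)), atol=1e-12)
    assert np.allclose(out[:, 3:], np.tile(right, (L, 1)), atol=1e-12)
    assert np.allclose(out, out[0], atol=1e-12)  # identical across rows


def test_complement_matches_triple_loop_oracle(align_params):
    rng = np.random.default_rng(6)
    L = 4
    seq, stc, _ = blocks_of(rng, L)
    amap = align(seq, stc, align_params)
    out = complement(amap, seq, stc, align_params).V.data
    a = amap.alpha.data
    A, B = seq.V.data, stc.V.data
    H2A, H2B = align_params.H2["Seq"].data, align_params.H2["Stc"].data
    left = np.zeros((L, A.shape[1]))
    right = np.zeros((L, B.shape[1]))
    for i in range(L):
        for j in range(L):
            left[i] += a[j, i] * A[j]      # (alpha^T A)_i
            right[i] += a[i, j] * B[j]     # (alpha B)_i
    expected = np.concatenate([left @ H2A, right @ H2B], axis=1)
    assert np.allclose(out, expected, atol=1e-12)


# ---------------------------------------------------------------------- fuse

def fusion_params(rng, dims, n=4, window=1):
    return FusionParams.create(rng, dims, n=n, window=window)


def test_fuse_zero_maps_isolate_one_block():
    rng = np.random.default_rng(7)
    fp = fusion_params(rng, {"F_seq_stc": 3, "F_seq_func": 3, "F_stc_func": 3})
    fp.W["F_seq_func"] = Tensor(np.zeros((3, 4)), True)
    fp.W["F_stc_func"] = Tensor(np.zeros((3, 4)), True)
    mk = lambda: FeatureBlock("F_seq_stc", Tensor(rng.normal(size=(5, 3))))
    b1 = mk()
    b2 = FeatureBlock("F_seq_func", Tensor(rng.normal(size=(5, 3))))
    b3 = FeatureBlock("F_stc_func", Tensor(rng.normal(size=(5, 3))))
    out = fuse({"F_seq_stc": b1, "F_seq_func": b2, "F_stc_func": b3}, fp).V.data
    assert np.allclose(out, b1.V.data @ fp.W["F_seq_stc"].data)


def test_fuse_is_additive():
    rng = np.random.default_rng(8)
    fp = fusion_params(rng, {"F_seq_stc": 3, "F_seq_func": 3, "F_stc_func": 3})
    mk = lambda role: FeatureBlock(role, Tensor(rng.normal(size=(5, 3))))
    A, Ap = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
    B, C = mk("F_seq_func"), mk("F_stc_func")
    zero = FeatureBlock("F_seq_func", Tensor(np.zeros((5, 3))))
    zero2 = FeatureBlock("F_stc_func", Tensor(np.zeros((5, 3))))
    f1 = fuse({"F_seq_stc": FeatureBlock("F_seq_stc", Tensor(A)),
               "F_seq_func": B, "F_stc_func": C}, fp).V.data
    f2 = fuse({"F_seq_stc": FeatureBlock("F_seq_stc", Tensor(Ap)),
               "F_seq_func": zero, "F_stc_func": zero2}, fp).V.data
    f12 = fuse({"F_seq_stc": FeatureBlock("F_seq_stc", Tensor(A + Ap)),
                "F_seq_func": B, "F_stc_func": C}, fp).V.data
    assert np.allclose(f1 + f2, f12, atol=1e-12)


def test_fuse_matches_explicit_arithmetic_3x2_toy():
    rng = np.random.default_rng(9)
    fp = fusion_params(rng, {"F_seq_stc": 2, "F_seq_func": 2, "F_stc_func": 2},
                       n=2)
    Vs = {r: rng.normal(size=(3, 2)) for r in fp.W}
    out = fuse({r: FeatureBlock(r, Tensor(V)) for r, V in Vs.items()}, fp).V.data
    expected = sum(Vs[r] @ fp.W[r].data for r in fp.W)
    assert np.allclose(out, expected, atol=1e-12)


# ----------------------------------------------------------------------- head

def test_zero_weights_give_half_propensity():
    rng = np.random.default_rng(10)
    fp = fusion_params(rng, {"F_seq_stc": 2}, n=2)
    fp.W_f = Tensor(np.zeros((2, 1)), True)
    fp.b_f = Tensor(np.zeros(1), True)
    F = FeatureBlock("F_fused", Tensor(rng.normal(size=(4, 2))))
    track = predict_propensities(F, fp, "p")
    assert np.allclose(track.P, 0.5)


def test_propensity_monotone_in_bias():
    rng = np.random.default_rng(11)
    fp = fusion_params(rng, {"F_seq_stc": 2}, n=2)
    F = FeatureBlock("F_fused", Tensor(rng.normal(size=(4, 2))))
    prev = None
    for bias in (-2.0, 0.0, 2.0, 10.0):
        fp.b_f = Tensor(np.array([bias]), True)
        p = predict_propensities(F, fp, "p").P
        if prev is not None:
            assert (p > prev).all()
        prev = p
    assert (prev > 0.99).all()


def test_propensity_closed_form_toy():
    """L=3, n=2, w=1: p_i = sigmoid(W_f . F_i + b) computed by hand."""
    fp = FusionParams({"F_seq_stc": Tensor(np.eye(2), True)},
                      Tensor(np.array([[0.5], [-1.0]]), True),
                      Tensor(np.array([0.25]), True), n=2, window=1)
    F = FeatureBlock("F_fused", Tensor(np.array([[1.0, 2.0],
                                                 [0.0, 0.0],
                                                 [-1.0, 0.5]])))
    p = predict_propensities(F, fp, "p").P
    logits = np.array([0.5 * 1 - 1 * 2 + 0.25, 0.25, -0.5 - 0.5 + 0.25])
    assert np.allclose(p, 1 / (1 + np.exp(-logits)), atol=1e-9)


def test_windowed_head_averages_context():
    fp = FusionParams({}, Tensor(np.array([[1.0]]), True),
                      Tensor(np.zeros(1), True), n=1, window=3)
    F = FeatureBlock("F_fused", Tensor(np.array([[0.0], [3.0], [6.0], [9.0]])))
    p = propensity_tensor(F, fp).data
    ctx = np.array([1.5, 3.0, 6.0, 7.5])  # edge windows average 2 rows
    assert np.allclose(p, 1 / (1 + np.exp(-ctx)), atol=1e-12)


# ----------------------------------------------------------- attention export

def test_attention_export_round_trip(tmp_path):
    a = np.array([[0.25, 0.75], [0.5, 0.5]])
    amap = AttentionMap("seq-stc", Tensor(a))
    path = tmp_path / "att.tsv"
    export_attention(amap, path)
    back = read_attention(path)
    assert np.allclose(back, a, atol=1e-8)
    assert np.abs(back.sum(axis=1) - 1.0).max() < 1e-6
    summary = (tmp_path / "att.tsv.summary.tsv").read_text().splitlines()
    args = [int(l.split("\t")[1]) - 1 for l in summary[1:]]
    assert args == list(a.argmax(axis=1))


# ------------------------------------------------- end-to-end gradient check

def test_end_to_end_gradients_match_finite_differences(tiny_model, small_proteome):
    """Profiles -> propensities -> summed BCE: backprop matches central
    differences for every trainable parameter on an L=6 toy."""
    rng = np.random.default_rng(12)
    src = small_proteome.items[0]
    from pclm.types import (ContactMap, LabelTrack, ProteinData,
                            ProteinRecord, SequenceProfile)
    L = 6
    rec = ProteinRecord("toy", src.record.sequence[:L])
    prof = SequenceProfile("toy", src.profile.X[:L].copy())
    Y = src.contacts.Y[:L, :L].copy()
    cm = ContactMap("toy", 0.5 * (Y + Y.T))
    y = np.array([1, 0, 1, 1, 0, 0])
    item = ProteinData(rec, prof, cm,
                       {"disorder": LabelTrack("toy", "disorder", y)})
    model = tiny_model

    def loss_fn():
        p = model.forward(item)
        return float(_bce_tensor(p, y.astype(float)).data)

    p = model.forward(item)
    loss = _bce_tensor(p, y.astype(float))
    loss.backward()
    params = model.parameters()
    worst = {}
    for name, t in params.items():
        num = finite_diff_grad(loss_fn, t.data)
        ana = t.grad if t.grad is not None else np.zeros_like(t.data)
        worst[name] = rel_err(num, ana)
    assert max(worst.values()) < 1e-4, worst
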