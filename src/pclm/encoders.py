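"""The three per-protein encoders: sequence, structure and function.

* Sequence: a bidirectional LSTM over the L x 40 evolutionary profile
  (20 PSSM log-odds columns ++ 20 profile-HMM emission columns); row i of the
  output concatenates the forward and backward hidden states at residue i.
* Structure: a bank of small 2D kernels convolved over the L x L contact map,
  pooled per residue (mean + max over the partner axis) and projected through
  an affine + relu layer, yielding a length-invariant L x d_stc block.
* Function: convolution of the one-hot sequence with frozen kernels copied
  from motif letter-probability matrices; only the per-motif bias trains.

Every encoder maps one protein to an L x d feature block and accepts any
length without reconfiguration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, glorot, lstm_direction, motif_conv
from .types import ContactMap, MotifPWM, SequenceProfile

__all__ = ["FeatureBlock", "EncoderParams", "encode_sequence",
           "encode_structure", "build_motif_kernels", "encode_function"]

ROLES = ("Seq", "Stc", "Func", "F_seq_stc", "F_seq_func", "F_stc_func", "F_fused")


@dataclass
class FeatureBlock:
    """An L x d feature matrix with its role in the pipeline."""

    role: str
    V: Tensor

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown feature-block role {self.role!r}")
        if not np.isfinite(self.V.data).all():
            raise ValueError("non-finite entries in feature block")

    @property
    def L(self) -> int:
        return self.V.data.shape[0]

    @property
    def d(self) -> int:
        return self.V.data.shape[1]


@dataclass
class EncoderParams:
    """Trainable parameters of the three encoders (all Tensors)."""

    lstm_hidden: int
    # forward / backward LSTM weights
    Wx_f: Tensor
    Wh_f: Tensor
    b_f: Tensor
    Wx_b: Tensor
    Wh_b: Tensor
    b_b: Tensor
    # structure encoder
    conv_kernels: Tensor        # (c, k, k)
    W_stc: Tensor               # (2c, d_stc)
    b_stc: Tensor               # (d_stc,)
    # function encoder
    motif_kernels: list[Tensor] = field(default_factory=list)  # frozen PWMs
    b_func: Tensor | None = None

    @staticmethod
    def create(rng: np.random.Generator, motifs: list[MotifPWM],
               d_in: int = 40, h: int = 32, c: int = 16, k: int = 5,
               d_stc: int = 32, trainable_motifs: bool = False) -> "EncoderParams":
        if k % 2 != 1:
            raise ValueError("structure kernel size must be odd")
        kernels = build_motif_kernels(motifs, trainable=trainable_motifs)
        return EncoderParams(
            lstm_hidden=h,
            Wx_f=Tensor(glorot(rng, (d_in, 4 * h)), True),
            Wh_f=Tensor(glorot(rng, (h, 4 * h)), True),
            b_f=Tensor(np.zeros(4 * h), True),
            Wx_b=Tensor(glorot(rng, (d_in, 4 * h)), True),
            Wh_b=Tensor(glorot(rng, (h, 4 * h)), True),
            b_b=Tensor(np.zeros(4 * h), True),
            conv_kernels=Tensor(glorot(rng, (c, k, k)) / k, True),
            W_stc=Tensor(glorot(rng, (2 * c, d_stc)), True),
            b_stc=Tensor(np.zeros(d_stc), True),
            motif_kernels=kernels,
            b_func=Tensor(np.zeros(len(kernels)), True),
        )

    def named(self, prefix: str = "enc") -> dict[str, Tensor]:
        out = {f"{prefix}.{n}": getattr(self, n)
               for n in ("Wx_f", "Wh_f", "b_f", "Wx_b", "Wh_b", "b_b",
                         "conv_kernels", "W_stc", "b_stc", "b_func")}
        for i, t in enumerate(self.motif_kernels):
            if t.requires_grad:
                out[f"{prefix}.motif_{i}"] = t
        return out


def encode_sequence(profile: SequenceProfile, params: EncoderParams) -> FeatureBlock:
    """Bi-LSTM over the evolutionary profile -> L x 2h block (role Seq)."""
    if profile.length < 1:
        raise ValueError("cannot encode an empty sequence")
    X = Tensor(profile.X)
    Hf = lstm_direction(X, params.Wx_f, params.Wh_f, params.b_f, reverse=False)
    Hb = lstm_direction(X, params.Wx_b, params.Wh_b, params.b_b, reverse=True)
    return FeatureBlock("Seq", Hf.concat_cols(Hb))


def encode_structure(contacts: ContactMap, params: EncoderParams) -> FeatureBlock:
    """Contact-map conv + per-residue pooling + affine relu -> L x d_stc (Stc).

    The per-residue pooling (mean and max over the partner axis of each of
    the c feature maps) turns the convolved L x L x c stack into an L x 2c
    summary, which the affine layer projects to d_stc; relu keeps the block
    non-negative.
    """
    k = params.conv_kernels.data.shape[-1]
    if contacts.length < k:
        raise ValueError(f"contact map shorter than kernel size {k}")
    Y = Tensor(contacts.Y)
    conv = Y.conv2d_bank(params.conv_kernels)       # (L, L, c)
    pooled = conv.rowpool_mean_max()                # (L, 2c)
    out = (pooled @ params.W_stc + params.b_stc).relu()
    return FeatureBlock("Stc", out)


def build_motif_kernels(motifs: list[MotifPWM],
                        trainable: bool = False) -> list[Tensor]:
    """Copy motif letter-probability matrices verbatim into convolution kernels.

    Kernels are frozen by default: the motif bank is prior knowledge, and only
    the per-motif bias is a trainable quantity.
    """
    if not motifs:
        raise ValueError("empty motif bank")
    return [Tensor(m.M.copy(), requires_grad=trainable) for m in motifs]


def encode_function(Z: np.ndarray, kernels: list[Tensor],
                    params: EncoderParams) -> FeatureBlock:
    """Motif-convolution of the one-hot sequence -> L x n_motifs block (Func).

    Each kernel is anchored at floor(l_m/2) with zero padding beyond the
    sequence ends, so a residue's activation reflects motifs covering it.
    """
    Z = np.asarray(Z, dtype=np.float64)
    if Z.ndim != 2 or Z.shape[1] != 20 or Z.shape[0] < 1:
        raise ValueError("one-hot input must be (L, 20) with L >= 1")
    if Z.sum(axis=1).max() > 1.0 + 1e-9:
        raise ValueError("one-hot rows must sum to at most 1")
    pre = motif_conv(Z, kernels, params.b_func)
    return FeatureBlock("Func", pre.relu())
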