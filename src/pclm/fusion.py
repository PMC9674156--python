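"""Attention-based alignment of feature blocks, cubic fusion, and the
sigmoid propensity head.

Two feature blocks A (L x d_A) and B (L x d_B) are aligned by projecting
each through a first-stage map and row-softmaxing the resulting L x L logit
matrix: alpha = softmax_rows((A H1_A)(B H1_B)^T).  Row i of alpha says how
residue i of A distributes attention over the residues of B.  The
complementary block concatenates the two attention-weighted summaries,
each projected through a second-stage map:

    F_AB = [ (alpha^T A) H2_A  ||  (alpha B) H2_B ]       (L x 2 d_c)

Cubic fusion sums the three pairwise complements through separate linear
maps, and the head applies a windowed position-wise logistic layer to give
per-residue propensities in (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .autodiff import Tensor, glorot
from .encoders import FeatureBlock
from .types import PropensityTrack

__all__ = ["AlignmentParams", "FusionParams", "AttentionMap", "align",
           "complement", "fuse", "predict_propensities", "export_attention"]

PAIR_ROLES = {("Seq", "Stc"): "F_seq_stc", ("Seq", "Func"): "F_seq_func",
              ("Stc", "Func"): "F_stc_func"}


@dataclass
class AttentionMap:
    """Row-stochastic L x L alignment weights between two feature blocks."""

    pair: str  # e.g. "seq-stc"
    alpha: Tensor

    def __post_init__(self):
        a = self.alpha.data
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("attention map must be square")
        if np.abs(a.sum(axis=1) - 1.0).max() > 1e-6:
            raise ValueError("attention rows must sum to 1")


@dataclass
class AlignmentParams:
    """First- and second-stage projections, one per encoder block.

    The same H1/H2 of a block is shared across every pair it takes part in.
    """

    H1: dict[str, Tensor]  # role -> (d_role, d_a)
    H2: dict[str, Tensor]  # role -> (d_role, d_c)
    d_a: int
    d_c: int
    scale_logits: bool = False
    literal_stc_func: bool = False

    @staticmethod
    def create(rng: np.random.Generator, dims: dict[str, int], d_a: int = 32,
               d_c: int = 32, scale_logits: bool = False,
               literal_stc_func: bool = False) -> "AlignmentParams":
        H1 = {r: Tensor(glorot(rng, (d, d_a)), True) for r, d in dims.items()}
        H2 = {r: Tensor(glorot(rng, (d, d_c)), True) for r, d in dims.items()}
        if literal_stc_func and dims.get("Stc") != dims.get("Func"):
            raise ValueError("the literal stc-func reading requires "
                             "d_stc == n_motifs")
        return AlignmentParams(H1, H2, d_a, d_c, scale_logits, literal_stc_func)

    def named(self, prefix: str = "alan") -> dict[str, Tensor]:
        out = {}
        for r, t in self.H1.items():
            out[f"{prefix}.H1_{r}"] = t
        for r, t in self.H2.items():
            out[f"{prefix}.H2_{r}"] = t
        return out


@dataclass
class FusionParams:
    """Cubic-fusion maps and the logistic output head."""

    W: dict[str, Tensor]   # pair role -> (d_pair_in, n)
    W_f: Tensor            # (n, 1)
    b_f: Tensor            # (1,)
    n: int
    window: int = 15

    @staticmethod
    def create(rng: np.random.Generator, in_dims: dict[str, int], n: int = 64,
               window: int = 15) -> "FusionParams":
        W = {r: Tensor(glorot(rng, (d, n)), True) for r, d in in_dims.items()}
        return FusionParams(W, Tensor(glorot(rng, (n, 1)), True),
                            Tensor(np.zeros(1), True), n, window)

    def named(self, prefix: str = "fuse") -> dict[str, Tensor]:
        out = {f"{prefix}.W_{r}": t for r, t in self.W.items()}
        out[f"{prefix}.W_f"] = self.W_f
        out[f"{prefix}.b_f"] = self.b_f
        return out


def align(A: FeatureBlock, B: FeatureBlock, params: AlignmentParams) -> AttentionMap:
    """Row-softmax attention between two blocks of the same protein."""
    if A.L != B.L:
        raise ValueError(f"row-count mismatch: {A.L} vs {B.L}")
    logits = (A.V @ params.H1[A.role]) @ (B.V @ params.H1[B.role]).T
    if params.scale_logits:
        logits = logits * (1.0 / np.sqrt(params.d_a))
    alpha = logits.row_softmax()
    return AttentionMap(f"{A.role.lower()}-{B.role.lower()}", alpha)


def complement(alpha: AttentionMap, A: FeatureBlock, B: FeatureBlock,
               params: AlignmentParams) -> FeatureBlock:
    """Attention-weighted complementary features of a block pair (L x 2 d_c)."""
    role = PAIR_ROLES.get((A.role, B.role))
    if role is None:
        raise ValueError(f"unsupported pair {(A.role, B.role)}")
    H2_A, H2_B = params.H2[A.role], params.H2[B.role]
    if params.literal_stc_func and role == "F_stc_func":
        # the printed form swaps the projections of this pair
        H2_A, H2_B = params.H2[B.role], params.H2[A.role]
    left = (alpha.alpha.T @ A.V) @ H2_A
    right = (alpha.alpha @ B.V) @ H2_B
    return FeatureBlock(role, left.concat_cols(right))


def fuse(blocks: dict[str, FeatureBlock], params: FusionParams) -> FeatureBlock:
    """Sum the complementary blocks through their fusion maps -> L x n."""
    Ls = {b.L for b in blocks.values()}
    if len(Ls) != 1:
        raise ValueError("all blocks must share the same length")
    out: Tensor | None = None
    for role, block in blocks.items():
        term = block.V @ params.W[role]
        out = term if out is None else out + term
    assert out is not None, "fuse requires at least one block"
    return FeatureBlock("F_fused", out)


def predict_propensities(F: FeatureBlock, params: FusionParams,
                         record_id: str = "") -> PropensityTrack:
    """Windowed position-wise logistic head over the fused block.

    Each residue's logit is W_f . mean(F rows in a width-w window centred at
    the residue) + b_f; w=1 reduces to a literal position-wise dense layer.
    """
    p = propensity_tensor(F, params)
    return PropensityTrack(record_id, p.data)


def propensity_tensor(F: FeatureBlock, params: FusionParams) -> Tensor:
    """Differentiable (L,) propensity vector — used by the training loop."""
    ctx = F.V.moving_mean_rows(params.window)
    logits = (ctx @ params.W_f + params.b_f).reshape(-1)
    return logits.sigmoid()


def export_attention(amap: AttentionMap, path) -> None:
    """Write the L x L weights as TSV plus a per-residue max-weight summary.

    The summary (``<path>.summary.tsv``) lists, for each row residue, the
    partner residue receiving maximal attention and that weight.
    """
    path = Path(path)
    a = amap.alpha.data
    np.savetxt(path, a, fmt="%.8f", delimiter="\t",
               header=f"pair={amap.pair} L={a.shape[0]}")
    arg = a.argmax(axis=1)
    with open(path.with_suffix(path.suffix + ".summary.tsv"), "w") as fh:
        fh.write("residue\tpartner_argmax\tmax_weight\n")
        for i in range(a.shape[0]):
            fh.write(f"{i + 1}\t{arg[i] + 1}\t{a[i, arg[i]]:.8f}\n")


def read_attention(path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t", ndmin=2)
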