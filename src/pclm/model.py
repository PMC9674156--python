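"""The full cubic model: three encoders, pairwise attention alignment,
cubic fusion and the logistic propensity head, with ablation switches.

Ablations mirror the architecture studies the model family is evaluated
with: dropping the structure encoder, dropping structure + function
(sequence only), and bypassing the alignment stage (encoder blocks feed the
fusion layer directly).  When fewer than two encoder blocks are active the
alignment stage has no pair to align and is bypassed automatically.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from .autodiff import Tensor
from .encoders import (EncoderParams, FeatureBlock, encode_function,
                       encode_sequence, encode_structure)
from .fusion import (AlignmentParams, AttentionMap, FusionParams, align,
                     complement, fuse, propensity_tensor)
from .types import MotifPWM, ProteinData

__all__ = ["ModelConfig", "PCLM"]


@dataclass
class ModelConfig:
    """Architecture hyper-parameters and ablation switches."""

    lstm_hidden: int = 32        # per direction
    conv_channels: int = 16
    kernel_size: int = 5
    d_stc: int = 32
    d_a: int = 32
    d_c: int = 32
    n_fused: int = 64
    window: int = 15             # width of the output head's context window
    use_stc: bool = True
    use_func: bool = True
    use_alan: bool = True
    scale_logits: bool = True
    literal_stc_func: bool = False
    trainable_motifs: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


class PCLM:
    """Sequence/structure/function cubic model for one-protein inputs."""

    def __init__(self, config: ModelConfig, motifs: list[MotifPWM],
                 seed: int = 0):
        self.config = config
        self.motifs = motifs
        rng = np.random.default_rng(seed)
        cfg = config
        self.enc = EncoderParams.create(
            rng, motifs, h=cfg.lstm_hidden, c=cfg.conv_channels,
            k=cfg.kernel_size, d_stc=cfg.d_stc,
            trainable_motifs=cfg.trainable_motifs)
        dims = {"Seq": 2 * cfg.lstm_hidden}
        if cfg.use_stc:
            dims["Stc"] = cfg.d_stc
        if cfg.use_func:
            dims["Func"] = len(motifs)
        self.block_dims = dims
        self.alan: AlignmentParams | None = None
        pairs = self._active_pairs()
        if cfg.use_alan and pairs:
            self.alan = AlignmentParams.create(
                rng, dims, d_a=cfg.d_a, d_c=cfg.d_c,
                scale_logits=cfg.scale_logits,
                literal_stc_func=cfg.literal_stc_func)
            fuse_dims = {role: 2 * cfg.d_c for _, _, role in pairs}
        else:
            # alignment bypass: encoder blocks feed fusion directly
            role_map = {"Seq": "F_seq_stc", "Stc": "F_seq_func",
                        "Func": "F_stc_func"}
            fuse_dims = {role_map[r]: d for r, d in dims.items()}
            self._bypass_roles = {r: role_map[r] for r in dims}
        self.fuseparams = FusionParams.create(rng, fuse_dims, n=cfg.n_fused,
                                              window=cfg.window)

    # ------------------------------------------------------------------

    def _active_pairs(self) -> list[tuple[str, str, str]]:
        pairs = []
        if self.config.use_stc:
            pairs.append(("Seq", "Stc", "F_seq_stc"))
        if self.config.use_func:
            pairs.append(("Seq", "Func", "F_seq_func"))
        if self.config.use_stc and self.config.use_func:
            pairs.append(("Stc", "Func", "F_stc_func"))
        return pairs

    def parameters(self) -> dict[str, Tensor]:
        out = self.enc.named()
        if self.alan is not None:
            out.update(self.alan.named())
        out.update(self.fuseparams.named())
        return out

    # ------------------------------------------------------------------

    def encode(self, item: ProteinData) -> dict[str, FeatureBlock]:
        blocks = {"Seq": encode_sequence(item.profile, self.enc)}
        if self.config.use_stc:
            blocks["Stc"] = encode_structure(item.contacts, self.enc)
        if self.config.use_func:
            blocks["Func"] = encode_function(item.record.one_hot(),
                                             self.enc.motif_kernels, self.enc)
        return blocks

    def forward(self, item: ProteinData, *, return_extras: bool = False):
        """Propensity Tensor of shape (L,); optionally the attention maps
        and the fused feature block as extras."""
        blocks = self.encode(item)
        attention: dict[str, AttentionMap] = {}
        if self.alan is not None:
            fused_in: dict[str, FeatureBlock] = {}
            for a, b, role in self._active_pairs():
                amap = align(blocks[a], blocks[b], self.alan)
                attention[amap.pair] = amap
                fused_in[role] = complement(amap, blocks[a], blocks[b], self.alan)
        else:
            fused_in = {self._bypass_roles[r]: blk for r, blk in blocks.items()}
        F = fuse(fused_in, self.fuseparams)
        p = propensity_tensor(F, self.fuseparams)
        if return_extras:
            return p, {"attention": attention, "fused": F, "blocks": blocks}
        return p

    def predict(self, item: ProteinData) -> np.ndarray:
        """Deterministic forward pass returning a plain (L,) score vector."""
        return self.forward(item).data

    # -- parameter state -------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {k: t.data.copy() for k, t in self.parameters().items()}
        for i, t in enumerate(self.enc.motif_kernels):
            out[f"motif_kernel_{i}"] = t.data.copy()
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        for k, t in params.items():
            if k not in state:
                raise KeyError(f"checkpoint missing parameter {k!r}")
            if state[k].shape != t.data.shape:
                raise ValueError(f"shape mismatch for {k!r}")
            t.data = np.array(state[k], dtype=np.float64)
        for i, t in enumerate(self.enc.motif_kernels):
            key = f"motif_kernel_{i}"
            if key in state:
                t.data = np.array(state[key], dtype=np.float64)
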