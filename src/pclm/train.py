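"""Training: summed binary cross-entropy loss, Adam optimisation one protein
at a time, disorder pre-training, function-specific fine-tuning, checkpoint
selection by minimum validation loss, and MCC-maximising threshold calibration.

The transfer protocol: the model is first pre-trained to predict disordered
residues (plentiful labels), then all layers are fine-tuned separately for
each of the five molecular function categories (scarce labels), giving five
independent checkpoints that run in parallel at prediction time.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Adam, Tensor
from .metrics import confusion_metrics
from .model import ModelConfig, PCLM
from .types import FUNCTIONS, LabelTrack, MotifPWM, PropensityTrack, ProteinData

__all__ = ["TrainConfig", "ModelCheckpoint", "bce_loss", "pretrain",
           "finetune", "select_threshold", "predict", "predict_functions",
           "save_checkpoint", "load_checkpoint"]

log = logging.getLogger("pclm.train")

EPS = 1e-7


@dataclass
class TrainConfig:
    stage: str = "pretrain"              # pretrain | finetune
    function_id: str | None = None
    learning_rate: float = 1e-3          # fine-tuning default is 1e-4
    epochs: int = 12
    seed: int = 0
    patience: int = 6                    # early stop after this many
    checkpoint_rule: str = "min_val_loss"
    finetune_scope: str = "all_layers"

    def __post_init__(self):
        if self.stage not in ("pretrain", "finetune"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.stage == "finetune":
            if self.function_id not in FUNCTIONS:
                raise ValueError("fine-tuning requires a valid function_id")
        if self.learning_rate <= 0 and self.learning_rate != 0.0:
            raise ValueError("learning rate must be non-negative")


@dataclass
class ModelCheckpoint:
    state: dict[str, np.ndarray]
    model_config: ModelConfig
    motifs: list[MotifPWM]
    provenance: str                      # pretrained | finetuned:<fn> | direct:<fn>
    validation_loss: float
    train_config: TrainConfig | None = None
    threshold: float | None = None
    history: list[dict] = field(default_factory=list)

    def build_model(self) -> PCLM:
        model = PCLM(self.model_config, self.motifs, seed=0)
        model.load_state_arrays(self.state)
        return model


def bce_loss(P, y) -> float:
    """Summed binary cross-entropy, -sum_i [y log p + (1-y) log(1-p)].

    Accepts PropensityTrack/LabelTrack or plain arrays; propensities are
    clipped to [1e-7, 1 - 1e-7] before the logarithm.
    """
    p = P.P if isinstance(P, PropensityTrack) else np.asarray(P, dtype=np.float64)
    t = y.y if isinstance(y, LabelTrack) else np.asarray(y, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError("propensity and label vectors must have equal length")
    p = np.clip(p, EPS, 1.0 - EPS)
    return float(-(t * np.log(p) + (1.0 - t) * np.log(1.0 - p)).sum())


def _bce_tensor(p: Tensor, y: np.ndarray) -> Tensor:
    yv = Tensor(np.asarray(y, dtype=np.float64))
    pc = p.clip(EPS, 1.0 - EPS)
    one = Tensor(np.ones_like(yv.data))
    return -((yv * pc.log() + (one - yv) * (one - pc).log()).sum())


def _epoch_losses(model: PCLM, corpus: list[ProteinData], track: str) -> float:
    """Mean per-protein summed BCE (no gradient)."""
    tot = 0.0
    for item in corpus:
        p = model.forward(item)
        tot += bce_loss(p.data, item.labels[track].y.astype(np.float64))
    return tot / len(corpus)


def _train(model: PCLM, corpus: list[ProteinData], val_corpus: list[ProteinData],
           config: TrainConfig, track: str) -> tuple[dict[str, np.ndarray], float,
                                                     list[dict]]:
    if not corpus or not val_corpus:
        raise ValueError("training and validation corpora must be non-empty")
    for item in corpus + val_corpus:
        if track not in item.labels:
            raise ValueError(f"record {item.record.id!r} lacks the "
                             f"{track!r} label track")
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    best_state = model.state_arrays()
    best_val = _epoch_losses(model, val_corpus, track)
    history: list[dict] = []
    bad_epochs = 0
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(corpus))
        train_tot = 0.0
        for idx in order:
            item = corpus[idx]
            opt.zero_grad()
            p = model.forward(item)
            loss = _bce_tensor(p, item.labels[track].y.astype(np.float64))
            train_tot += float(loss.data)
            if config.learning_rate > 0:
                loss.backward()
                opt.step()
        val = _epoch_losses(model, val_corpus, track)
        if not np.isfinite(val):
            raise RuntimeError(f"validation loss became non-finite at epoch "
                               f"{epoch}; aborting")
        history.append({"epoch": epoch, "train_loss": train_tot / len(corpus),
                        "val_loss": val})
        log.info("epoch %d train_loss=%.4f val_loss=%.4f", epoch,
                 train_tot / len(corpus), val)
        if val < best_val:
            best_val = val
            best_state = model.state_arrays()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                log.info("early stop after %d non-improving epochs", bad_epochs)
                break
    return best_state, best_val, history


def pretrain(corpus: list[ProteinData], val_corpus: list[ProteinData],
             config: TrainConfig, model_config: ModelConfig,
             motifs: list[MotifPWM]) -> ModelCheckpoint:
    """Pre-train on disorder labels; returns the epoch-minimum-validation model."""
    if config.stage != "pretrain":
        raise ValueError("config.stage must be 'pretrain'")
    _check_disjoint(corpus, val_corpus)
    model = PCLM(model_config, motifs, seed=config.seed)
    state, val, history = _train(model, corpus, val_corpus, config, "disorder")
    return ModelCheckpoint(state, model_config, motifs, "pretrained", val,
                           config, history=history)


def finetune(source: ModelCheckpoint, corpus: list[ProteinData],
             val_corpus: list[ProteinData], config: TrainConfig,
             direct: bool = False) -> ModelCheckpoint:
    """Fine-tune all layers for one function; or train from scratch (direct)."""
    if config.stage != "finetune":
        raise ValueError("config.stage must be 'finetune'")
    fn = config.function_id
    if not direct and source.provenance != "pretrained":
        raise ValueError("fine-tuning requires a pretrained source checkpoint "
                         "(or direct=True)")
    _check_disjoint(corpus, val_corpus)
    model = PCLM(source.model_config, source.motifs, seed=config.seed)
    if not direct:
        model.load_state_arrays(source.state)
    state, val, history = _train(model, corpus, val_corpus, config, fn)
    provenance = f"direct:{fn}" if direct else f"finetuned:{fn}"
    return ModelCheckpoint(state, source.model_config, source.motifs,
                           provenance, val, config, history=history)


def _check_disjoint(corpus, val_corpus) -> None:
    train_ids = {i.record.id for i in corpus}
    val_ids = {i.record.id for i in val_corpus}
    if train_ids & val_ids:
        raise ValueError(f"train/validation record ids overlap: "
                         f"{sorted(train_ids & val_ids)[:3]}...")


def select_threshold(tracks: list[PropensityTrack],
                     labels: list[LabelTrack]) -> float:
    """Threshold maximising MCC over pooled residue scores.

    Candidates are the midpoints of consecutive distinct scores plus {0, 1};
    ties are broken toward the smaller threshold (higher sensitivity).
    """
    scores = np.concatenate([t.P for t in tracks])
    y = np.concatenate([l.y for l in labels])
    if scores.shape != y.shape:
        raise ValueError("pooled scores and labels must have equal length")
    if y.min() == y.max():
        raise ValueError("both classes must be present to calibrate a threshold")
    uniq = np.unique(scores)
    cands = np.r_[0.0, (uniq[:-1] + uniq[1:]) / 2.0, 1.0]
    best_thr, best_mcc = 0.0, -np.inf
    for thr in cands:
        calls = (scores > thr).astype(np.int64)
        tp = int(((calls == 1) & (y == 1)).sum())
        tn = int(((calls == 0) & (y == 0)).sum())
        fp = int(((calls == 1) & (y == 0)).sum())
        fn = int(((calls == 0) & (y == 1)).sum())
        denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / denom
        if mcc > best_mcc + 1e-15:
            best_mcc, best_thr = mcc, float(thr)
    return best_thr


def predict(checkpoint: ModelCheckpoint, item: ProteinData) -> PropensityTrack:
    """Deterministic forward pass of one checkpoint on one protein."""
    model = checkpoint.build_model()
    scores = model.predict(item)
    return PropensityTrack(item.record.id, scores, checkpoint.threshold)


def predict_functions(checkpoints: dict[str, ModelCheckpoint],
                      item: ProteinData) -> list[PropensityTrack]:
    """Run the five function checkpoints in parallel; fixed function order."""
    missing = [f for f in FUNCTIONS if f not in checkpoints]
    if missing:
        raise ValueError(f"missing checkpoints for {missing}")
    return [predict(checkpoints[f], item) for f in FUNCTIONS]


# ---------------------------------------------------------------------------
# checkpoint files: a .npz of parameter arrays plus a JSON sidecar of metadata


def save_checkpoint(ckpt: ModelCheckpoint, path) -> None:
    path = Path(path)
    np.savez(path, **ckpt.state)
    meta = {
        "model_config": ckpt.model_config.to_dict(),
        "provenance": ckpt.provenance,
        "validation_loss": ckpt.validation_loss,
        "threshold": ckpt.threshold,
        "history": ckpt.history,
        "motifs": [{"name": m.name, "matrix": m.M.tolist()} for m in ckpt.motifs],
        "train_config": (vars(ckpt.train_config).copy()
                         if ckpt.train_config else None),
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh)


def load_checkpoint(path) -> ModelCheckpoint:
    path = Path(path)
    if not path.suffix:
        path = path.with_suffix(".npz")
    with np.load(path) as npz:
        state = {k: npz[k] for k in npz.files}
    with open(path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    motifs = [MotifPWM(m["name"], np.array(m["matrix"])) for m in meta["motifs"]]
    tc = TrainConfig(**meta["train_config"]) if meta["train_config"] else None
    return ModelCheckpoint(state, ModelConfig(**meta["model_config"]), motifs,
                           meta["provenance"], meta["validation_loss"], tc,
                           meta["threshold"], meta.get("history", []))
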