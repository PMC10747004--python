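"""Dataset splitting, training loop and presentation-attack metrics.

The split is finger-disjoint and stratified by label: no finger identity
appears in both the training and validation sets.  Training minimises cross
entropy with Adam under cosine learning-rate annealing.  Metrics follow the
ISO/IEC 30107-3 conventions:

* ``APCER_s``: fraction of species-s attack presentations classified bona fide,
* ``BPCER``:   fraction of bona fide presentations classified attack,
* ``ACR``:     overall fraction correct, equivalently
  ``1 - (sum_s APCER_s * N_s + BPCER * N_BF) / N_total``.

Class encoding: 0 = bona fide, 1 = attack; the decision is attack iff the
attack-class probability exceeds the threshold (default 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .nn import Adam, Tensor, cosine_lr, cross_entropy, softmax

__all__ = ["TrainConfig", "Confusion", "EvalResult", "split_dataset",
           "train", "predict_proba", "metrics_from_confusion", "evaluate",
           "LABELS"]

LABELS = {"bona_fide": 0, "attack": 1}


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings (defaults follow the full-scale protocol:
    batch 32, 300 epochs, Adam at 1e-4 under cosine annealing, cross
    entropy; reduced runs override epochs/lr)."""

    batch_size: int = 32
    workers: int = 8
    epochs: int = 300
    lr: float = 1e-4
    lr_min: float = 1e-6
    betas: tuple[float, float] = (0.9, 0.999)
    seed: int = 0

    def __post_init__(self):
        if self.batch_size <= 0 or self.epochs <= 0 or self.lr <= 0:
            raise ValueError("batch_size, epochs and lr must be positive")


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def split_dataset(manifest: pd.DataFrame, ratio: float = 0.8, seed: int = 0
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Finger-disjoint, label-stratified train/validation split.

    Within each label the clips are grouped by ``finger_id`` and whole
    fingers are assigned to the training side until its clip count reaches
    ``ratio`` of the label's clips (within 1 when group sizes allow).
    Deterministic in `seed`.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    val_idx: list[int] = []
    for label, group in manifest.groupby("label", sort=True):
        fingers = {fid: list(idx.index)
                   for fid, idx in group.groupby("finger_id", sort=True)}
        if len(fingers) < 2:
            raise ValueError(
                f"label {label!r} has {len(fingers)} finger(s); need >= 2 "
                "for a finger-disjoint split")
        order = list(fingers)
        rng.shuffle(order)
        target = ratio * len(group)
        count = 0
        tr_groups: list = []
        va_groups: list = []
        for fid in order:
            members = fingers[fid]
            # assign the whole finger to whichever side keeps the count closest
            if abs(count + len(members) - target) <= abs(count - target) \
                    and count < target:
                tr_groups.append(fid)
                count += len(members)
            else:
                va_groups.append(fid)
        # both sides must see every label (small manifests can starve one)
        if not va_groups:
            va_groups.append(tr_groups.pop())
        if not tr_groups:
            tr_groups.append(va_groups.pop(0))
        for fid in tr_groups:
            train_idx.extend(fingers[fid])
        for fid in va_groups:
            val_idx.extend(fingers[fid])
    tr = manifest.loc[sorted(train_idx)]
    va = manifest.loc[sorted(val_idx)]
    if set(tr.finger_id) & set(va.finger_id):
        raise AssertionError("finger leakage across the split")
    return tr.reset_index(drop=True), va.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def predict_proba(model: nn.Module, X: np.ndarray,
                  batch_size: int = 64) -> np.ndarray:
    """Softmax class probabilities, (n, num_classes)."""
    model.eval()
    out = []
    for i in range(0, len(X), batch_size):
        logits = model(Tensor(X[i:i + batch_size]))
        out.append(softmax(logits, axis=1).data)
    return np.concatenate(out, axis=0)


def train(model: nn.Module, train_data: tuple[np.ndarray, np.ndarray],
          val_data: tuple[np.ndarray, np.ndarray] | None = None,
          config: TrainConfig = TrainConfig()) -> tuple[nn.Module, dict]:
    """Fit `model` on (X, y) arrays; returns (model, history).

    History records per-epoch mean training loss, training accuracy, the
    learning rate used, and validation accuracy when `val_data` is given.
    """
    X, y = train_data
    if len(X) == 0:
        raise ValueError("empty training data")
    y = np.asarray(y, dtype=np.int64)
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.lr, betas=config.betas)
    history: dict[str, list] = {"loss": [], "train_acc": [], "lr": []}
    if val_data is not None:
        history["val_acc"] = []

    for epoch in range(config.epochs):
        opt.lr = cosine_lr(config.lr, epoch, config.epochs, config.lr_min)
        model.train()
        order = rng.permutation(len(X))
        losses, correct = [], 0
        for i in range(0, len(X), config.batch_size):
            idx = order[i:i + config.batch_size]
            logits = model(Tensor(X[idx]))
            loss = cross_entropy(logits, y[idx])
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            correct += int((logits.data.argmax(1) == y[idx]).sum())
        history["loss"].append(float(np.mean(losses)))
        history["train_acc"].append(correct / len(X))
        history["lr"].append(opt.lr)
        if val_data is not None:
            proba = predict_proba(model, val_data[0], config.batch_size)
            acc = float((proba.argmax(1) == np.asarray(val_data[1])).mean())
            history["val_acc"].append(acc)
    model.eval()
    return model, history


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class Confusion:
    """Raw decision counts: bona fide presentations (total / rejected) and,
    per PAI species, attack presentations (total / accepted as bona fide)."""

    n_bf: int
    bf_rejected: int
    attacks: dict[str, tuple[int, int]] = field(default_factory=dict)

    def total(self) -> int:
        return self.n_bf + sum(n for n, _ in self.attacks.values())


@dataclass
class EvalResult:
    acr: float
    apcer_by_species: dict[str, float]
    apcer_max: float
    bpcer: float
    confusion: Confusion

    def as_dict(self) -> dict:
        return {"acr": self.acr, "apcer_max": self.apcer_max,
                "bpcer": self.bpcer,
                "apcer_by_species": dict(self.apcer_by_species)}


def metrics_from_confusion(confusion: Confusion) -> EvalResult:
    """ACR / APCER per species (worst case as ``apcer_max``) / BPCER."""
    n_attack_total = sum(n for n, _ in confusion.attacks.values())
    if confusion.n_bf <= 0 and n_attack_total <= 0:
        raise ValueError("confusion has no presentations")
    apcer = {s: (acc / n if n else 0.0)
             for s, (n, acc) in confusion.attacks.items()}
    bpcer = confusion.bf_rejected / confusion.n_bf if confusion.n_bf else 0.0
    errors = confusion.bf_rejected + sum(acc for _, acc
                                         in confusion.attacks.values())
    total = confusion.total()
    acr = 1.0 - errors / total
    apcer_max = max(apcer.values(), default=0.0)
    return EvalResult(acr=acr, apcer_by_species=apcer, apcer_max=apcer_max,
                      bpcer=bpcer, confusion=confusion)


def evaluate(model: nn.Module, X: np.ndarray, y: np.ndarray,
             species: list[str] | None = None,
             threshold: float = 0.5) -> EvalResult:
    """Evaluate a trained model: decision = attack iff the attack-class
    probability exceeds `threshold`; aggregates via
    :func:`metrics_from_confusion`."""
    if len(X) == 0:
        raise ValueError("empty evaluation data")
    y = np.asarray(y, dtype=np.int64)
    if species is None:
        species = ["unknown" if lbl == 1 else "none" for lbl in y]
    proba = predict_proba(model, X)
    decided_attack = proba[:, 1] > threshold

    bf = y == 0
    conf = Confusion(n_bf=int(bf.sum()),
                     bf_rejected=int((bf & decided_attack).sum()))
    for s in sorted({sp for sp, lbl in zip(species, y) if lbl == 1}):
        sel = np.array([sp == s for sp in species]) & (y == 1)
        conf.attacks[s] = (int(sel.sum()),
                           int((sel & ~decided_attack).sum()))
    return metrics_from_confusion(conf)
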