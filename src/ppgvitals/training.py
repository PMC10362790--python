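"""Dataset splitting, masked pretraining, and per-patient fine-tuning.

Splitting is patient-level: a patient's slices are never shared between the
training, validation, and test sets.  Within each test patient the slices
are ordered chronologically and the earliest 20% is used for fine-tuning
while the remaining 80% is held out for evaluation — later data never
informs earlier predictions, which is the leakage guard the personalization
protocol depends on.

Pretraining minimizes the masked-reconstruction MSE (random contiguous spans
zeroed, the encoder asked to restore them); fine-tuning re-attaches a
regression head and continues with the supervised MSE at learning rate 3e-3
for up to 200 epochs, with multiplicative learning-rate decay after epoch 50
and early stopping once the validation loss has not improved for 20
consecutive epochs.  The optimizer is Adam with default moments.

Regression targets are z-scored during optimization: the pooled model uses
its training cohort's label statistics, while a personalized model uses the
patient's own fine-tune-train statistics — the scaled-down analogue of
adapting to a patient's operating point when only a handful of fine-tuning
slices exist.  Predictions are always returned in physical units.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .emd import ChannelizedSlice
from .model import (
    ModelConfig,
    TimeSeriesTransformer,
    mask_for_mlm,
    mlm_loss,
    regression_loss,
    standardize,
)

__all__ = [
    "SplitSpec",
    "TrainConfig",
    "Adam",
    "split_patients",
    "chronological_split",
    "build_split",
    "pretrain",
    "masked_reconstruction_mse",
    "train_regression",
    "predict_targets",
    "finetune_personalize",
    "PersonalizationResult",
]

TARGET_FIELDS = {"ASBP": "asbp", "ADBP": "adbp", "SpO2": "spo2"}


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 200
    lr: float = 3e-3
    decay_start_epoch: int = 50
    decay_beta: float = 0.98
    patience: int = 20
    batch_size: int = 64
    seed: int = 0
    min_slices_per_patient: int = 10
    mask_ratio: float = 0.15
    mask_mean_span: float = 3.0
    #: optional pretraining crop mixture: ((length, batch_size, weight), ...)
    crop_curriculum: tuple[tuple[int, int, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.lr <= 0:
            raise ValueError("lr must be > 0")

    def lr_at(self, epoch: int) -> float:
        """Learning rate for a 1-based epoch (decays after decay_start_epoch)."""
        if epoch <= self.decay_start_epoch:
            return self.lr
        return self.lr * self.decay_beta ** (epoch - self.decay_start_epoch)


@dataclass
class SplitSpec:
    """Patient-level split plus per-test-patient chronological partitions."""

    train_patients: tuple[str, ...]
    val_patients: tuple[str, ...]
    test_patients: tuple[str, ...]
    excluded: dict[str, str] = field(default_factory=dict)
    #: patient -> (finetune slice indices, eval slice indices) into the
    #: dataset this split was built from, each chronologically ordered
    test_partitions: dict[str, tuple[list[int], list[int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sets = [set(self.train_patients), set(self.val_patients), set(self.test_patients)]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValueError(f"patient sets overlap: {sets[i] & sets[j]}")

    def to_json(self) -> str:
        d = asdict(self)
        d["test_partitions"] = {k: [list(a), list(b)] for k, (a, b) in self.test_partitions.items()}
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SplitSpec":
        d = json.loads(text)
        d["train_patients"] = tuple(d["train_patients"])
        d["val_patients"] = tuple(d["val_patients"])
        d["test_patients"] = tuple(d["test_patients"])
        d["test_partitions"] = {
            k: (list(a), list(b)) for k, (a, b) in d["test_partitions"].items()
        }
        return cls(**d)


def split_patients(
    slice_counts: Mapping[str, int],
    fractions: tuple[float, float, float] = (0.70, 0.10, 0.20),
    seed: int = 0,
    min_slices_per_patient: int = 10,
) -> SplitSpec:
    """Randomly assign patients to train/validation/test sets.

    Patients with fewer than ``min_slices_per_patient`` qualified slices
    (fewer than 200 s of usable signal at the 20-s slice length) are excluded
    with a logged reason.  Set sizes follow round(fraction * n) with the test
    set absorbing the remainder.
    """
    if not math.isclose(sum(fractions), 1.0):
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    eligible = sorted(pid for pid, n in slice_counts.items() if n >= min_slices_per_patient)
    excluded = {
        pid: f"only {n} slices (< {min_slices_per_patient})"
        for pid, n in slice_counts.items()
        if n < min_slices_per_patient
    }
    if len(eligible) < 3:
        raise ValueError(f"need at least 3 eligible patients, got {len(eligible)}")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(eligible))
    n = len(order)
    n_train = max(1, int(round(fractions[0] * n)))
    n_val = max(1, int(round(fractions[1] * n)))
    n_train = min(n_train, n - 2)
    n_val = min(n_val, n - n_train - 1)
    return SplitSpec(
        train_patients=tuple(order[:n_train]),
        val_patients=tuple(order[n_train : n_train + n_val]),
        test_patients=tuple(order[n_train + n_val :]),
        excluded=excluded,
    )


def _slice_time(s: ChannelizedSlice) -> tuple[str, int]:
    return (s.record_id, s.start_sample)


def chronological_split(
    slices: Sequence, finetune_frac: float = 0.2
) -> tuple[list, list]:
    """Split one patient's slices into (finetune, eval) chronologically.

    Slices are sorted by start time; the earliest ``floor(frac * n)`` (at
    least 1) go to fine-tuning and the rest to evaluation, so no evaluation
    slice precedes any fine-tuning slice.
    """
    if len(slices) < 2:
        raise ValueError(f"need at least 2 slices, got {len(slices)}")
    if not 0 < finetune_frac < 1:
        raise ValueError(f"finetune_frac must be in (0, 1), got {finetune_frac}")
    ordered = sorted(slices, key=_slice_time)
    k = max(1, int(math.floor(finetune_frac * len(ordered))))
    return ordered[:k], ordered[k:]


def build_split(
    slices: Sequence[ChannelizedSlice],
    fractions: tuple[float, float, float] = (0.70, 0.10, 0.20),
    seed: int = 0,
    min_slices_per_patient: int = 10,
    finetune_frac: float = 0.2,
) -> SplitSpec:
    """Patient-level split of a slice dataset, with per-test-patient
    chronological fine-tune/eval index partitions."""
    by_patient: dict[str, list[int]] = {}
    for i, s in enumerate(slices):
        by_patient.setdefault(s.subject_id, []).append(i)
    spec = split_patients(
        {pid: len(idx) for pid, idx in by_patient.items()},
        fractions=fractions,
        seed=seed,
        min_slices_per_patient=min_slices_per_patient,
    )
    for pid in spec.test_patients:
        idx = sorted(by_patient[pid], key=lambda i: _slice_time(slices[i]))
        k = max(1, int(math.floor(finetune_frac * len(idx))))
        spec.test_partitions[pid] = (idx[:k], idx[k:])
    return spec


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: dict, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# Pretraining (masked reconstruction)
# ---------------------------------------------------------------------------

def _standardized_stack(slices: Sequence[ChannelizedSlice]) -> np.ndarray:
    return np.stack([standardize(s.channels)[0] for s in slices])


def pretrain(
    slices: Sequence[ChannelizedSlice],
    model_config: ModelConfig,
    train_config: TrainConfig | None = None,
    model: TimeSeriesTransformer | None = None,
    dtype=np.float64,
) -> tuple[TimeSeriesTransformer, list[float]]:
    """Unsupervised masked-reconstruction pretraining.

    With ``crop_curriculum`` unset each epoch is one shuffled pass over the
    full-length slices.  With a curriculum, each optimization step draws a
    crop length (and matching batch size) from the configured mixture and
    trains on random crops of that length: short crops make optimization
    steps cheap, so the reconstruction circuit forms quickly, while the
    longer entries adapt the full range of the learnable positional
    encodings — with absolute positional encodings every position's
    attention pattern is learned separately, which is why full-length-only
    training converges far more slowly.

    Returns the best-by-training-loss model and the per-epoch loss history.
    Deterministic under ``train_config.seed``.
    """
    if len(slices) == 0:
        raise ValueError("pretraining requires a nonempty slice set")
    tc = train_config or TrainConfig()
    rng = np.random.default_rng(tc.seed)
    model = model or TimeSeriesTransformer(
        model_config, seed=int(rng.integers(2**31 - 1)), dtype=dtype
    )
    X = _standardized_stack(slices).astype(model.dtype, copy=False)
    n = len(X)
    curriculum = tc.crop_curriculum
    if curriculum is not None:
        lengths = [c[0] for c in curriculum]
        batches = [c[1] for c in curriculum]
        probs = np.array([c[2] for c in curriculum], dtype=float)
        probs /= probs.sum()
        if max(lengths) > X.shape[2]:
            raise ValueError("crop length exceeds slice length")
    opt = Adam(model.params)
    history: list[float] = []
    best_loss, best_params = np.inf, None
    steps_per_epoch = max(1, n // tc.batch_size)
    for epoch in range(1, tc.epochs + 1):
        lr = tc.lr_at(epoch)
        losses = []
        if curriculum is None:
            order = rng.permutation(n)
            batch_plan = [
                (X[order[b0 : b0 + tc.batch_size]], None)
                for b0 in range(0, n, tc.batch_size)
            ]
        else:
            batch_plan = []
            for _ in range(steps_per_epoch):
                k = int(rng.choice(len(lengths), p=probs))
                L, B = lengths[k], min(batches[k], n)
                idx = rng.choice(n, B, replace=False)
                starts = rng.integers(0, X.shape[2] - L + 1, size=B)
                batch_plan.append(
                    (np.stack([X[i, :, s0 : s0 + L] for i, s0 in zip(idx, starts)]), L)
                )
        for xb, _L in batch_plan:
            masked = np.empty_like(xb)
            masks = np.zeros((len(xb), xb.shape[2]), dtype=bool)
            for j in range(len(xb)):
                masked[j], masks[j] = mask_for_mlm(
                    xb[j], tc.mask_ratio, tc.mask_mean_span, seed=rng
                )
            rec, cache = model.reconstruct(
                masked, train=True, rng=rng, return_cache=True, mlm_mask=masks
            )
            loss, dg = mlm_loss(rec, xb, masks, return_grad=True)
            grads = model.backward_mlm(dg.astype(model.dtype, copy=False), cache)
            opt.step(model.params, grads, lr)
            losses.append(loss)
        epoch_loss = float(np.mean(losses))
        history.append(epoch_loss)
        if epoch_loss < best_loss:
            best_loss = epoch_loss
            best_params = {k: v.copy() for k, v in model.params.items()}
    if best_params is not None:
        model.params = best_params
    return model, history


def masked_reconstruction_mse(
    model: TimeSeriesTransformer,
    slices: Sequence[ChannelizedSlice],
    mask_ratio: float = 0.15,
    mask_mean_span: float = 3.0,
    seed: int = 0,
) -> float:
    """Held-out masked-reconstruction MSE (no dropout, fixed masks)."""
    rng = np.random.default_rng(seed)
    X = _standardized_stack(slices).astype(model.dtype, copy=False)
    losses = []
    for x in X:
        masked, mask = mask_for_mlm(x, mask_ratio, mask_mean_span, seed=rng)
        rec = model.reconstruct(masked[None], mlm_mask=mask[None])
        losses.append(mlm_loss(rec[0], x, mask))
    return float(np.mean(losses))


# ---------------------------------------------------------------------------
# Supervised regression (pooled training and per-patient fine-tuning)
# ---------------------------------------------------------------------------

def _labels(slices: Sequence[ChannelizedSlice], targets: tuple[str, ...]) -> np.ndarray:
    out = np.empty((len(slices), len(targets)))
    for j, t in enumerate(targets):
        fieldname = TARGET_FIELDS[t]
        for i, s in enumerate(slices):
            v = getattr(s, fieldname)
            if v is None:
                raise ValueError(f"slice {i} is missing target {t}")
            out[i, j] = v
    return out


def _label_stats(y: np.ndarray, fallback: dict | None = None) -> dict[str, np.ndarray]:
    mean = y.mean(axis=0)
    sd = y.std(axis=0)
    if fallback is not None:
        sd = np.where(sd < 1e-6, fallback["sd"], sd)
    sd = np.where(sd < 1e-6, 1.0, sd)
    return {"mean": mean, "sd": sd}


def train_regression(
    model: TimeSeriesTransformer,
    train_slices: Sequence[ChannelizedSlice],
    train_config: TrainConfig | None = None,
    val_slices: Sequence[ChannelizedSlice] | None = None,
    label_stats: dict[str, np.ndarray] | None = None,
) -> tuple[TimeSeriesTransformer, dict]:
    """Supervised MSE training of encoder + regression head.

    With a validation set, early-stops after ``patience`` epochs without
    improvement and restores the best-validation parameters; otherwise the
    best-training-loss parameters are kept.  ``label_stats`` (z-scoring
    statistics for the targets) defaults to the training labels' own moments
    and is recorded in the returned info dict.
    """
    if len(train_slices) == 0:
        raise ValueError("regression training requires a nonempty training set")
    tc = train_config or TrainConfig()
    targets = model.config.targets
    rng = np.random.default_rng(tc.seed)
    X = _standardized_stack(train_slices).astype(model.dtype, copy=False)
    y_raw = _labels(train_slices, targets)
    stats = label_stats or _label_stats(y_raw)
    y = ((y_raw - stats["mean"]) / stats["sd"]).astype(model.dtype)
    have_val = val_slices is not None and len(val_slices) > 0
    if have_val:
        Xv = _standardized_stack(val_slices).astype(model.dtype, copy=False)
        yv = ((_labels(val_slices, targets) - stats["mean"]) / stats["sd"]).astype(model.dtype)
    opt = Adam(model.params)
    history, val_history = [], []
    best_score, best_params, best_epoch = np.inf, None, 0
    n = len(X)
    epochs_run = 0
    for epoch in range(1, tc.epochs + 1):
        epochs_run = epoch
        lr = tc.lr_at(epoch)
        order = rng.permutation(n)
        losses = []
        for b0 in range(0, n, tc.batch_size):
            idx = order[b0 : b0 + tc.batch_size]
            yb, cache = model.predict(X[idx], train=True, rng=rng, return_cache=True)
            loss, dg = regression_loss(yb, y[idx], return_grad=True)
            grads = model.backward_regression(dg.astype(model.dtype, copy=False), cache)
            opt.step(model.params, grads, lr)
            losses.append(loss)
        history.append(float(np.mean(losses)))
        if have_val:
            yv_hat = model.predict(Xv)
            score = regression_loss(yv_hat, yv)
            val_history.append(float(score))
        else:
            score = history[-1]
        if score < best_score - 1e-12:
            best_score, best_epoch = score, epoch
            best_params = {k: v.copy() for k, v in model.params.items()}
        elif have_val and epoch - best_epoch >= tc.patience:
            break
    if best_params is not None:
        model.params = best_params
    info = {
        "history": history,
        "val_history": val_history,
        "label_stats": stats,
        "epochs_run": epochs_run,
        "best_epoch": best_epoch,
    }
    return model, info


def predict_targets(
    model: TimeSeriesTransformer,
    slices: Sequence[ChannelizedSlice],
    label_stats: dict[str, np.ndarray],
    batch_size: int = 64,
) -> np.ndarray:
    """Predict physical-unit targets for a slice list: (N, n_targets)."""
    X = _standardized_stack(slices).astype(model.dtype, copy=False)
    outs = []
    for b0 in range(0, len(X), batch_size):
        outs.append(model.predict(X[b0 : b0 + batch_size]))
    z = np.concatenate(outs) if outs else np.empty((0, model.config.n_targets))
    return z * label_stats["sd"] + label_stats["mean"]


@dataclass
class PersonalizationResult:
    patient_id: str
    model: TimeSeriesTransformer
    eval_slices: list
    predictions: np.ndarray  # (n_eval, n_targets), physical units
    label_stats: dict[str, np.ndarray]
    info: dict


def finetune_personalize(
    pretrained: TimeSeriesTransformer,
    patient_slices: Sequence[ChannelizedSlice],
    train_config: TrainConfig | None = None,
    finetune_frac: float = 0.2,
    val_frac: float = 0.2,
    pooled_label_stats: dict[str, np.ndarray] | None = None,
    head_params: dict[str, np.ndarray] | None = None,
) -> PersonalizationResult:
    """Personalize the pretrained encoder for one patient.

    The patient's slices are split chronologically (earliest
    ``finetune_frac`` for fine-tuning, the rest for evaluation); the last
    ``val_frac`` of the fine-tune portion is held out as the early-stopping
    validation set so the evaluation slices are never touched during
    training.  Parameters are initialized from the pretrained model (the
    regression head optionally warm-started from a pooled head); predictions
    on the evaluation slices come from the best-validation checkpoint.
    """
    if len(patient_slices) == 0:
        raise ValueError("fine-tuning requires a nonempty slice set")
    tc = train_config or TrainConfig()
    finetune, eval_slices = chronological_split(patient_slices, finetune_frac)
    n_val = max(1, int(math.floor(val_frac * len(finetune))))
    if n_val >= len(finetune):
        ft_train, ft_val = finetune, finetune
    else:
        ft_train, ft_val = finetune[:-n_val], finetune[-n_val:]

    model = pretrained.copy()
    if head_params is not None:
        for k, v in head_params.items():
            model.params[k] = v.copy()
    y_train = _labels(ft_train, model.config.targets)
    stats = _label_stats(y_train, fallback=pooled_label_stats)
    model, info = train_regression(
        model, ft_train, train_config=tc, val_slices=ft_val, label_stats=stats
    )
    predictions = predict_targets(model, eval_slices, stats)
    patient_id = patient_slices[0].subject_id
    return PersonalizationResult(
        patient_id=patient_id,
        model=model,
        eval_slices=list(eval_slices),
        predictions=predictions,
        label_stats=stats,
        info=info,
    )
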