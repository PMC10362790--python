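"""End-to-end study pipelines on synthetic cohorts.

These functions wire the full chain — cohort synthesis, QC, EMD
channelization, masked pretraining, pooled regression, per-patient
fine-tuning, compliance evaluation — at a desk-scale problem size chosen so
the whole study runs in minutes on one CPU: 25 Hz sampling (a 20-s slice is
500 samples), a 3-layer encoder with d_model 32, and a 30-patient cohort
with ~500 pretraining slices.  The scientific structure (pipeline order,
split protocol, losses, early stopping) is identical to the full-scale
configuration; only the problem size is reduced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .emd import ChannelizedSlice, channelize
from .evaluation import PairedPredictions, compliance_report
from .model import ModelConfig, TimeSeriesTransformer
from .qc import QCConfig, preprocess_record
from .synth import CohortConfig, generate_cohort
from .training import (
    TrainConfig,
    build_split,
    finetune_personalize,
    masked_reconstruction_mse,
    predict_targets,
    pretrain,
    train_regression,
)

__all__ = ["StudyConfig", "build_channelized_cohort", "personalization_study"]


@dataclass(frozen=True)
class StudyConfig:
    """Scaled-down study conditions (see module docstring)."""

    n_patients: int = 30
    duration_s: float = 500.0
    fs: float = 25.0
    n_channels: int = 4
    cohort: CohortConfig = field(default_factory=CohortConfig)
    model: ModelConfig = field(default_factory=lambda: ModelConfig(
        n_layers=3, d_model=32, n_heads=2, d_ff=64, head_hidden=128,
        dropout=0.0, max_len=500, n_channels=4,
        targets=("ASBP", "ADBP", "SpO2"),
    ))
    pretrain_epochs: int = 130
    pretrain_batch: int = 32
    #: crop mixture for pretraining steps: (length, batch, weight)
    pretrain_curriculum: tuple[tuple[int, int, float], ...] = (
        (125, 32, 0.60),
        (250, 16, 0.25),
        (500, 8, 0.15),
    )
    max_pretrain_slices: int = 500
    pooled_epochs: int = 15
    pooled_patience: int = 5
    finetune: TrainConfig = field(default_factory=lambda: TrainConfig(
        epochs=200, lr=3e-3, decay_start_epoch=50, decay_beta=0.98,
        patience=20, batch_size=64,
    ))


def build_channelized_cohort(
    seed: int, study: StudyConfig | None = None
) -> tuple[list[ChannelizedSlice], dict]:
    """Synthesize a cohort, run QC, and channelize every qualified slice.

    Returns the channelized slices and a summary dict (per-record QC
    outcomes and the generating patient specs).
    """
    cfg = study or StudyConfig()
    cohort = generate_cohort(cfg.n_patients, cfg.duration_s, cfg.fs, seed, cfg.cohort)
    qc_cfg = QCConfig()
    slices: list[ChannelizedSlice] = []
    reports = {}
    specs = {}
    for record, spec in cohort:
        qualified, report = preprocess_record(record, qc_cfg)
        reports[record.record_id] = report
        specs[spec.patient_id] = spec
        for qs in qualified:
            slices.append(channelize(qs, n_channels=cfg.n_channels))
    return slices, {"qc_reports": reports, "patient_specs": specs}


def personalization_study(seed: int, study: StudyConfig | None = None) -> dict:
    """Run the full pretraining + personalization pipeline on one cohort.

    Steps: build the synthetic cohort and its channelized slices; split
    patients 70/10/20; pretrain the encoder by masked reconstruction on the
    training patients' slices; quantify pretraining utility as the held-out
    masked-reconstruction MSE of the pretrained vs a freshly initialized
    encoder; train a pooled regression model (training patients, validation
    patients for early stopping); personalize per test patient on the
    chronologically earliest 20% of their slices; and evaluate both models on
    the later 80%.

    Returns a dict with per-target MAEs, the per-patient win fraction of
    personalization over the pooled model, the pretraining MSE ratio, and
    compliance reports for the personalized predictions.
    """
    cfg = study or StudyConfig()
    rng = np.random.default_rng(seed)
    slices, meta = build_channelized_cohort(int(rng.integers(2**31 - 1)), cfg)
    split = build_split(slices, seed=int(rng.integers(2**31 - 1)))

    by_patient: dict[str, list[ChannelizedSlice]] = {}
    for s in slices:
        by_patient.setdefault(s.subject_id, []).append(s)
    train_slices = [s for p in split.train_patients for s in by_patient[p]]
    val_slices = [s for p in split.val_patients for s in by_patient[p]]
    if len(train_slices) > cfg.max_pretrain_slices:
        train_slices = train_slices[: cfg.max_pretrain_slices]

    pre_tc = TrainConfig(
        epochs=cfg.pretrain_epochs,
        batch_size=cfg.pretrain_batch,
        seed=int(rng.integers(2**31 - 1)),
        crop_curriculum=cfg.pretrain_curriculum,
    )
    pretrained, pre_history = pretrain(train_slices, cfg.model, pre_tc, dtype=np.float32)

    mse_seed = int(rng.integers(2**31 - 1))
    random_model = TimeSeriesTransformer(
        cfg.model, seed=int(rng.integers(2**31 - 1)), dtype=np.float32
    )
    mse_pretrained = masked_reconstruction_mse(pretrained, val_slices, seed=mse_seed)
    mse_random = masked_reconstruction_mse(random_model, val_slices, seed=mse_seed)

    pooled_tc = TrainConfig(
        epochs=cfg.pooled_epochs,
        patience=cfg.pooled_patience,
        batch_size=cfg.pretrain_batch,
        seed=int(rng.integers(2**31 - 1)),
    )
    pooled, pooled_info = train_regression(
        pretrained.copy(), train_slices, pooled_tc, val_slices=val_slices
    )
    pooled_stats = pooled_info["label_stats"]

    targets = cfg.model.targets
    per_patient = []
    all_y, all_personal, all_pooled, all_subject = [], [], [], []
    ft_seed = int(rng.integers(2**31 - 1))
    for k, pid in enumerate(split.test_patients):
        tc = TrainConfig(
            epochs=cfg.finetune.epochs,
            lr=cfg.finetune.lr,
            decay_start_epoch=cfg.finetune.decay_start_epoch,
            decay_beta=cfg.finetune.decay_beta,
            patience=cfg.finetune.patience,
            batch_size=cfg.finetune.batch_size,
            seed=ft_seed + k,
        )
        result = finetune_personalize(
            pretrained,
            by_patient[pid],
            train_config=tc,
            pooled_label_stats=pooled_stats,
            head_params={k2: v for k2, v in pooled.params.items() if k2.startswith("head.")},
        )
        y_true = np.column_stack(
            [
                [getattr(s, {"ASBP": "asbp", "ADBP": "adbp", "SpO2": "spo2"}[t]) for s in result.eval_slices]
                for t in targets
            ]
        )
        pooled_pred = predict_targets(pooled, result.eval_slices, pooled_stats)
        mae_personal = np.mean(np.abs(result.predictions - y_true), axis=0)
        mae_pooled = np.mean(np.abs(pooled_pred - y_true), axis=0)
        per_patient.append(
            {
                "patient_id": pid,
                "n_eval": len(result.eval_slices),
                "mae_personalized": mae_personal,
                "mae_pooled": mae_pooled,
                "epochs_run": result.info["epochs_run"],
            }
        )
        all_y.append(y_true)
        all_personal.append(result.predictions)
        all_pooled.append(pooled_pred)
        all_subject.extend([pid] * len(result.eval_slices))

    y = np.vstack(all_y)
    personal = np.vstack(all_personal)
    pooled_p = np.vstack(all_pooled)
    subjects = np.asarray(all_subject)

    reports = {}
    for j, t in enumerate(targets):
        p = PairedPredictions(y=y[:, j], y_hat=personal[:, j], subject_id=subjects, target=t)
        reports[t] = compliance_report(p)

    asbp_idx = targets.index("ASBP")
    wins = [
        pp["mae_personalized"][asbp_idx] < pp["mae_pooled"][asbp_idx] for pp in per_patient
    ]
    return {
        "n_slices": len(slices),
        "n_pretrain_slices": len(train_slices),
        "split": split,
        "pretrain_history": pre_history,
        "mse_pretrained": mse_pretrained,
        "mse_random": mse_random,
        "pretrain_mse_ratio": mse_random / mse_pretrained,
        "per_patient": per_patient,
        "mae_personalized": {
            t: float(np.mean(np.abs(personal[:, j] - y[:, j]))) for j, t in enumerate(targets)
        },
        "mae_pooled": {
            t: float(np.mean(np.abs(pooled_p[:, j] - y[:, j]))) for j, t in enumerate(targets)
        },
        "personalization_win_fraction": float(np.mean(wins)),
        "compliance": reports,
        "meta": meta,
    }
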