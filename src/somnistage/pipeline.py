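"""End-to-end synthetic experiment driver.

Chains every stage of the package on synthetic polysomnography: simulate a
cohort of nights, run QC and filtering, extract spectral stacks, train the
multi-epoch LSTM (optionally two of them for decision fusion), and evaluate
on a held-out synthetic night.  Used by the command-line ``run-synthetic``
command and by the reproducibility script.

Profiles fix the problem size.  The ``desk`` profile — 64 LSTM cells,
mini-batches of 128, six training nights of 340 epochs (~2,000 samples) and
one held-out night — is sized for a single CPU core; the ``full`` profile
carries the full-scale configuration (512 cells, Table-style batch size) and
is only practical with substantially more compute.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np

from .evaluation import EvalResult, evaluate
from .features import build_sequence_dataset, compute_stacks
from .fusion import fuse_series
from .model import (
    LSTMClassifier,
    ModelConfig,
    TrainConfig,
    TrainingTrace,
    class_weights,
    make_minibatches,
    train,
)
from .qc import run_qc
from .record import PSGRecord, QCReport
from .synthetic import default_hypnogram_model, default_templates, generate_hypnogram, synthesize_record

logger = logging.getLogger(__name__)


@dataclass
class Profile:
    """Problem-size bundle for the synthetic experiment."""

    n_train_nights: int
    epochs_per_night: int
    test_epochs: int
    n_cells: int
    batch_size: int
    group_size: int
    max_epochs: int


PROFILES = {
    "desk": Profile(
        n_train_nights=6, epochs_per_night=340, test_epochs=360,
        n_cells=64, batch_size=128, group_size=3, max_epochs=15,
    ),
    "full": Profile(
        n_train_nights=6, epochs_per_night=960, test_epochs=960,
        n_cells=512, batch_size=1024, group_size=10, max_epochs=200,
    ),
}


def simulate_cohort(
    n_nights: int, epochs_per_night: int, seed: int, sampling_rate: float = 125.0
) -> list[PSGRecord]:
    """Simulate ``n_nights`` independent synthetic subjects."""
    base = np.random.default_rng(seed)
    records = []
    for _ in range(n_nights):
        s1, s2 = base.integers(2**31, size=2)
        model = default_hypnogram_model(epochs_per_night)
        hyp = generate_hypnogram(model, int(s1))
        records.append(
            synthesize_record(hyp, default_templates(), sampling_rate=sampling_rate, seed=int(s2))
        )
    return records


def prepare_datasets(records: list[PSGRecord], mode: int):
    """QC + feature extraction + mode-``i`` sequence assembly per subject."""
    per_subject = []
    for rec in records:
        filtered, qc = run_qc(rec)
        feats = compute_stacks(filtered, qc)
        X, y, idx = build_sequence_dataset(feats, mode)
        per_subject.append((X, y, idx, qc))
    return per_subject


def _pool(per_subject):
    X = np.concatenate([s[0] for s in per_subject])
    y = np.concatenate([s[1] for s in per_subject])
    groups = {i: None for i in range(len(per_subject))}
    offset = 0
    for i, s in enumerate(per_subject):
        groups[i] = np.arange(offset, offset + len(s[0]))
        offset += len(s[0])
    return X, y, groups


def train_mode(
    train_subjects,
    test_subjects,
    mode: int,
    profile: Profile,
    seed: int,
) -> tuple[LSTMClassifier, TrainingTrace]:
    """Train one mode-``i`` network under the profile's protocol."""
    X, y, groups = _pool(train_subjects)
    Xe, ye, _ = _pool(test_subjects)
    cfg = TrainConfig(
        max_epochs=profile.max_epochs,
        batch_size=profile.batch_size,
        group_size=profile.group_size,
        seed=seed,
    )
    batches = make_minibatches(groups, cfg.batch_size, cfg.group_size, seed=seed)
    model = LSTMClassifier(ModelConfig(n_cells=profile.n_cells, mode=mode), seed=seed + 1)
    weights = class_weights(np.bincount(y, minlength=5))
    t0 = time.perf_counter()
    trace = train(model, X, y, batches, Xe, ye, cfg, weights=weights)
    logger.info("mode-%d training: %d epochs in %.1f s (stop: %s)",
                mode, len(trace.train_costs), time.perf_counter() - t0, trace.stop_reason)
    return model, trace


def run_synthetic(
    seed: int,
    mode: int = 3,
    profile: str | Profile = "desk",
    with_fusion: bool = False,
) -> dict:
    """Full synthetic experiment; returns models, traces and evaluation results.

    The held-out subject's night never contributes to training; the testing
    cost that drives early stopping is computed on it, mirroring a
    train/test split by subject.
    """
    prof = PROFILES[profile] if isinstance(profile, str) else profile
    records = simulate_cohort(prof.n_train_nights, prof.epochs_per_night, seed=seed)
    test_records = simulate_cohort(1, prof.test_epochs, seed=seed + 10_007)

    out: dict = {"profile": prof, "seed": seed}
    modes = sorted({mode, 2}) if with_fusion else [mode]
    per_mode = {}
    for m in modes:
        tr = prepare_datasets(records, m)
        te = prepare_datasets(test_records, m)
        model, trace = train_mode(tr, te, m, prof, seed)
        Xe, ye, _ = _pool(te)
        proba = model.predict_proba(Xe)
        epochs = te[0][2]
        per_mode[m] = {
            "model": model, "trace": trace, "proba": proba,
            "epochs": epochs, "labels": ye,
        }
        n_night = test_records[0].n_epochs
        result = evaluate(ye, np.argmax(proba, axis=1), coverage=len(ye) / n_night)
        per_mode[m]["eval"] = result
        logger.info("mode-%d held-out accuracy %.3f kappa %s",
                    m, result.accuracy, f"{result.kappa:.3f}" if result.kappa else "n/a")
    out["per_mode"] = per_mode
    out["test_hypnogram"] = test_records[0].hypnogram

    if with_fusion:
        pm3, pm2 = per_mode[mode], per_mode[2]
        fused = fuse_series(pm3["proba"], pm3["epochs"], pm2["proba"], pm2["epochs"])
        truth = test_records[0].hypnogram[fused["epoch"].to_numpy()]
        n_night = test_records[0].n_epochs
        out["fusion"] = {
            "decisions": fused,
            "eval": evaluate(truth, fused["label"].to_numpy(), coverage=len(fused) / n_night),
        }
    return out
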