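"""STFT spectral-stack features for 30 s PSG epochs.

Each retained epoch is reduced to a 32x32x4 tensor: 32 STFT time frames by 32
frequency bins (0 to ~24 Hz) for four derived channels (EEG = C3/C4 average,
EOG-L, EOG-R, EMG).  The STFT uses a 128-point Hamming window sliding in steps
of 90 samples over the 3000-sample (100 Hz) epoch — 38 points of overlap,
giving exactly ``floor((3000-128)/90)+1 = 32`` frames at a 900 ms frame step
and a bin width of ``100/128 = 0.78125`` Hz.  Magnitudes of each time frame
are min-max normalized to [0, 1] independently, so only spectral *shape*
within a frame reaches the classifier.

Classifier inputs concatenate the spectral stacks of ``i`` consecutive epochs
(input mode ``i`` in 1..4) along the time axis and flatten frequency x channel
into 128 columns, yielding an ``(i*32) x 128`` matrix whose last 32 rows always
belong to the target epoch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .qc import EPOCH_SAMPLES, TARGET_RATE, resample_epoch
from .record import EEG_ROLES, EOG_ROLES, PSGRecord, QCReport

logger = logging.getLogger(__name__)

WINDOW_LENGTH = 128
HOP = 90
N_FRAMES = 32
N_BINS = 32
#: Derived-channel order of the stack's last axis.
CHANNEL_ORDER = ("EEG", "EOG-L", "EOG-R", "EMG")

_window = np.hamming(WINDOW_LENGTH)


class RecordRejectedError(ValueError):
    """Raised when QC left no usable channel derivation for a record."""


def derive_analysis_channels(record: PSGRecord, qc: QCReport) -> dict[str, np.ndarray]:
    """Resolve the four analysis channels with drop fallbacks.

    EEG is the C3/C4 average when both survive, else the surviving one; if one
    EOG channel was dropped both EOG slots carry the survivor's data; EMG
    passes through.  Records with both EEG channels dropped, both EOG channels
    dropped, or EMG dropped are rejected.
    """
    dropped = qc.dropped_roles
    live_eeg = [r for r in EEG_ROLES if r not in dropped]
    live_eog = [r for r in EOG_ROLES if r not in dropped]
    if not live_eeg:
        raise RecordRejectedError("record rejected: both C3 and C4 dropped")
    if not live_eog:
        raise RecordRejectedError("record rejected: both EOG channels dropped")
    if "EMG" in dropped:
        raise RecordRejectedError("record rejected: EMG channel dropped")

    if len(live_eeg) == 2:
        if record.meta["C3"].sampling_rate != record.meta["C4"].sampling_rate:
            raise ValueError("C3 and C4 must share a sampling rate to be averaged")
        eeg = (record.channels["C3"] + record.channels["C4"]) / 2.0
        eeg_rate = record.meta["C3"].sampling_rate
    else:
        eeg = record.channels[live_eeg[0]]
        eeg_rate = record.meta[live_eeg[0]].sampling_rate

    out = {"EEG": np.asarray(eeg, dtype=float)}
    rates = {"EEG": eeg_rate}
    for slot in EOG_ROLES:
        src = slot if slot in live_eog else live_eog[0]
        out[slot] = np.asarray(record.channels[src], dtype=float)
        rates[slot] = record.meta[src].sampling_rate
    out["EMG"] = np.asarray(record.channels["EMG"], dtype=float)
    rates["EMG"] = record.meta["EMG"].sampling_rate
    out["_rates"] = rates  # type: ignore[assignment]
    return out


def compute_spectrogram(x: np.ndarray) -> np.ndarray:
    """32x32 normalized magnitude spectrogram of one 3000-sample epoch.

    Frames start at samples 0, 90, ..., 2790; each is Hamming-windowed and
    transformed with a 128-point FFT; one-sided bins 0-31 are kept; each time
    frame is then min-max normalized to [0, 1] independently.  A degenerate
    frame (max == min, e.g. an all-zero epoch) maps to all zeros.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (EPOCH_SAMPLES,):
        raise ValueError(f"expected {EPOCH_SAMPLES} samples, got {x.shape}")
    idx = np.arange(N_FRAMES)[:, None] * HOP + np.arange(WINDOW_LENGTH)[None, :]
    frames = x[idx] * _window
    mag = np.abs(np.fft.rfft(frames, n=WINDOW_LENGTH, axis=1))[:, :N_BINS]
    lo = mag.min(axis=1, keepdims=True)
    hi = mag.max(axis=1, keepdims=True)
    span = hi - lo
    out = np.zeros_like(mag)
    ok = span[:, 0] > 0
    out[ok] = (mag[ok] - lo[ok]) / span[ok]
    return out


def stack_channels(spectra: dict[str, np.ndarray]) -> np.ndarray:
    """Stack the four per-channel spectrograms into a 32x32x4 tensor."""
    arrs = []
    for name in CHANNEL_ORDER:
        s = np.asarray(spectra[name], dtype=float)
        if s.shape != (N_FRAMES, N_BINS):
            raise ValueError(f"{name} spectrogram has shape {s.shape}, expected (32, 32)")
        arrs.append(s)
    return np.stack(arrs, axis=-1)


def flatten_stack(stack: np.ndarray) -> np.ndarray:
    """Flatten (T, 32, 4) -> (T, 128); column index = 32*channel + bin."""
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[1:] != (N_BINS, len(CHANNEL_ORDER)):
        raise ValueError(f"expected a (T, 32, 4) stack, got {stack.shape}")
    return np.transpose(stack, (0, 2, 1)).reshape(stack.shape[0], N_BINS * len(CHANNEL_ORDER))


@dataclass
class FeatureSet:
    """Epoch-indexed spectral stacks for one record.

    ``stacks``: (n_retained, 32, 32, 4); ``epoch_indices``: original 0-based
    epoch index of each stack; ``labels``: stage per retained epoch (or None);
    ``qc_mask``: boolean over the whole night, True where the epoch survived.
    """

    stacks: np.ndarray
    epoch_indices: np.ndarray
    qc_mask: np.ndarray
    labels: np.ndarray | None = None

    def save(self, path) -> None:
        payload = {
            "stacks": self.stacks,
            "epoch_indices": self.epoch_indices,
            "qc_mask": self.qc_mask,
        }
        if self.labels is not None:
            payload["labels"] = self.labels
        np.savez_compressed(path, **payload)

    @classmethod
    def load(cls, path) -> "FeatureSet":
        with np.load(path) as z:
            return cls(
                stacks=z["stacks"],
                epoch_indices=z["epoch_indices"],
                qc_mask=z["qc_mask"],
                labels=z["labels"] if "labels" in z else None,
            )


def compute_stacks(record: PSGRecord, qc: QCReport) -> FeatureSet:
    """Derive channels, resample retained epochs to 100 Hz, and build stacks."""
    derived = derive_analysis_channels(record, qc)
    rates = derived.pop("_rates")
    n_ep = record.n_epochs
    mask = qc.retained_mask(n_ep)
    stacks, kept = [], []
    for k in range(n_ep):
        if not mask[k]:
            continue
        spectra = {}
        for name in CHANNEL_ORDER:
            fs = rates[name]
            spe = int(round(fs * 30))
            seg = derived[name][k * spe : (k + 1) * spe]
            seg = resample_epoch(seg, fs, TARGET_RATE)
            spectra[name] = compute_spectrogram(seg)
        stacks.append(stack_channels(spectra))
        kept.append(k)
    labels = None
    if record.hypnogram is not None:
        labels = record.hypnogram[np.array(kept, dtype=int)] if kept else np.empty(0, dtype=int)
    return FeatureSet(
        stacks=np.array(stacks) if stacks else np.empty((0, N_FRAMES, N_BINS, 4)),
        epoch_indices=np.array(kept, dtype=int),
        qc_mask=mask,
        labels=labels,
    )


def assemble_sequence(features: FeatureSet, target_epoch: int, mode: int) -> np.ndarray | None:
    """Mode-``i`` input for one target epoch, or None when history is missing.

    Requires epochs ``t-i+1 .. t`` to exist and all to be QC-retained;
    otherwise the sample is skipped (logged, not raised).
    """
    if mode not in (1, 2, 3, 4):
        raise ValueError("mode must be in 1..4")
    t = int(target_epoch)
    if t - mode + 1 < 0:
        logger.debug("epoch %d skipped: fewer than %d preceding epochs", t, mode - 1)
        return None
    needed = list(range(t - mode + 1, t + 1))
    pos = {int(e): i for i, e in enumerate(features.epoch_indices)}
    if any(e not in pos for e in needed):
        logger.debug("epoch %d skipped: QC gap inside its %d-epoch context", t, mode)
        return None
    parts = [flatten_stack(features.stacks[pos[e]]) for e in needed]
    return np.concatenate(parts, axis=0)


def build_sequence_dataset(
    features: FeatureSet, mode: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All mode-``i`` samples of a record: (X, labels, target epoch indices).

    X has shape (n_samples, i*32, 128); the label of a sample is the stage of
    its target (last) epoch.  Night edges and QC gaps are skipped.
    """
    if features.labels is None:
        raise ValueError("feature set carries no stage labels")
    xs, ys, idx = [], [], []
    for i, t in enumerate(features.epoch_indices):
        seq = assemble_sequence(features, int(t), mode)
        if seq is None:
            continue
        xs.append(seq)
        ys.append(int(features.labels[i]))
        idx.append(int(t))
    n_rows = 32 * mode
    if not xs:
        return (
            np.empty((0, n_rows, N_BINS * 4)),
            np.empty(0, dtype=int),
            np.empty(0, dtype=int),
        )
    return np.stack(xs), np.array(ys, dtype=int), np.array(idx, dtype=int)
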