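"""Quality control and preprocessing for overnight PSG records.

The pipeline mirrors standard practice for large sleep cohorts:

1. whole-night electrode-drop detection — a channel whose mean absolute
   amplitude over the entire night exceeds half its declared physical
   acquisition maximum is discarded;
2. role-specific zero-phase band-pass filtering (FIR, Hamming design, applied
   forward and reverse) on the surviving channels;
3. per-epoch artifact rejection on the filtered data — a 30 s epoch is
   excluded when both central EEG channels, or both EOG channels, or the EMG
   channel exceed the declared physical maximum in mean absolute amplitude;
4. per-epoch resampling to the 100 Hz analysis rate.

Filtering runs on the whole night before epoching, so the 51-tap edge
transients appear only once at the ends of the recording rather than inside
every epoch.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .record import EEG_ROLES, EOG_ROLES, EPOCH_SECONDS, ROLES, PSGRecord, QCReport

#: Band-pass edges (Hz) per channel role.
PASSBANDS = {
    "C3": (0.3, 45.0),
    "C4": (0.3, 45.0),
    "EOG-L": (0.3, 12.0),
    "EOG-R": (0.3, 12.0),
    "EMG": (0.3, 20.0),
}

#: FIR filter order; taps = order + 1.
FIR_ORDER = 50

#: Analysis sampling rate after resampling (Hz); 30 s epochs become 3000 samples.
TARGET_RATE = 100
EPOCH_SAMPLES = TARGET_RATE * EPOCH_SECONDS


def design_fir(role: str, sampling_rate: float) -> np.ndarray:
    """51-tap Hamming-window FIR band-pass for the role's frequency range."""
    lo, hi = PASSBANDS[role]
    nyq = sampling_rate / 2
    if hi >= nyq:
        raise ValueError(
            f"{role} passband upper edge {hi} Hz is not below Nyquist "
            f"({nyq} Hz at {sampling_rate} Hz sampling)"
        )
    return sps.firwin(FIR_ORDER + 1, [lo, hi], window="hamming", pass_zero=False, fs=sampling_rate)


def bandpass_filter(x: np.ndarray, role: str, sampling_rate: float) -> np.ndarray:
    """Zero-phase band-pass: filter, reverse, filter again, reverse.

    The two passes cancel the FIR's phase and square its magnitude response.
    Output length equals input length.
    """
    x = np.asarray(x, dtype=float)
    b = design_fir(role, sampling_rate)
    if len(x) <= 3 * len(b):
        raise ValueError(f"signal of {len(x)} samples too short for a {len(b)}-tap filter")
    y = sps.lfilter(b, 1.0, x)
    y = sps.lfilter(b, 1.0, y[::-1])[::-1]
    return y


def detect_dropped_channels(record: PSGRecord) -> QCReport:
    """Whole-night drop rule: mean |x| strictly above half the physical max."""
    report = QCReport()
    for role in ROLES:
        x = record.channels[role]
        if len(x) == 0:
            raise ValueError(f"channel {role} is empty")
        mean_abs = float(np.mean(np.abs(x)))
        if mean_abs > 0.5 * record.meta[role].physical_max:
            report.dropped_channels[role] = mean_abs
    return report


def _epoch_mean_abs(record: PSGRecord, role: str) -> np.ndarray:
    fs = record.meta[role].sampling_rate
    spe = int(round(fs * EPOCH_SECONDS))
    x = record.channels[role][: record.n_epochs * spe]
    return np.abs(x).reshape(record.n_epochs, spe).mean(axis=1)


def reject_epochs(record: PSGRecord, dropped: QCReport | None = None) -> QCReport:
    """Per-epoch rejection on filtered data.

    An epoch is excluded when both channels of the EEG pair, or both of the
    EOG pair, or the EMG channel exceed their declared physical maximum in
    mean absolute amplitude.  A pair with one whole-night-dropped member
    degrades to a test on the surviving channel alone; a fully dropped pair
    (or dropped EMG) contributes no exclusions here — such records are
    rejected at channel derivation.
    """
    dropped_roles = dropped.dropped_roles if dropped is not None else set()
    report = QCReport()
    n_ep = record.n_epochs

    exceeds = {
        role: _epoch_mean_abs(record, role) > record.meta[role].physical_max
        for role in ROLES
        if role not in dropped_roles
    }

    def pair_exceeds(roles: tuple[str, str]) -> np.ndarray:
        live = [r for r in roles if r in exceeds]
        if not live:
            return np.zeros(n_ep, dtype=bool)
        out = np.ones(n_ep, dtype=bool)
        for r in live:
            out &= exceeds[r]
        return out

    reasons = [
        ("EEG-pair", pair_exceeds(EEG_ROLES)),
        ("EOG-pair", pair_exceeds(EOG_ROLES)),
        ("EMG", exceeds.get("EMG", np.zeros(n_ep, dtype=bool))),
    ]
    for reason, mask in reasons:
        for k in np.flatnonzero(mask):
            report.excluded_epochs.setdefault(int(k), reason)
    return report


def filter_record(record: PSGRecord, dropped: QCReport | None = None) -> PSGRecord:
    """Apply the role-specific zero-phase band-pass to every non-dropped channel."""
    dropped_roles = dropped.dropped_roles if dropped is not None else set()
    channels = {}
    for role in ROLES:
        x = record.channels[role]
        if role in dropped_roles:
            channels[role] = np.array(x, dtype=float)
        else:
            channels[role] = bandpass_filter(x, role, record.meta[role].sampling_rate)
    return PSGRecord(channels, dict(record.meta), record.hypnogram)


def run_qc(record: PSGRecord) -> tuple[PSGRecord, QCReport]:
    """Full QC pass: drop detection, filtering, per-epoch rejection.

    Returns the filtered record and the merged QC report.  Running the result
    through QC again yields the identical report (idempotence).
    """
    record = record.truncate_to_epoch_grid()
    dropped = detect_dropped_channels(record)
    filtered = filter_record(record, dropped)
    epochs = reject_epochs(filtered, dropped)
    return filtered, dropped.merge(epochs)


def resample_epoch(x: np.ndarray, from_rate: float, to_rate: int = TARGET_RATE) -> np.ndarray:
    """Resample one 30 s epoch to the analysis rate (3000 samples at 100 Hz).

    Polyphase rational resampling with the built-in anti-aliasing low-pass at
    the target Nyquist.
    """
    x = np.asarray(x, dtype=float)
    expected = int(round(from_rate * EPOCH_SECONDS))
    if len(x) != expected:
        raise ValueError(
            f"expected a 30 s epoch of {expected} samples at {from_rate} Hz, got {len(x)}"
        )
    if from_rate == to_rate:
        return x.copy()
    ratio = Fraction(to_rate) / Fraction(from_rate).limit_denominator(100_000)
    y = sps.resample_poly(x, ratio.numerator, ratio.denominator)
    n_out = to_rate * EPOCH_SECONDS
    if len(y) > n_out:
        y = y[:n_out]
    elif len(y) < n_out:
        y = np.pad(y, (0, n_out - len(y)), mode="edge")
    return y
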