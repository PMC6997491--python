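"""Core containers for polysomnography records and QC results.

A night of polysomnography is held as one :class:`PSGRecord`: a mapping from
channel role (C3, C4, EOG-L, EOG-R, EMG) to a sample array in microvolts plus
per-channel metadata.  The unit of sleep staging is the 30 s epoch; the epoch
grid is 0-based with epoch ``k`` covering the half-open interval
``[30k, 30(k+1))`` seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Channel roles every record must carry, in canonical order.
ROLES = ("C3", "C4", "EOG-L", "EOG-R", "EMG")

EEG_ROLES = ("C3", "C4")
EOG_ROLES = ("EOG-L", "EOG-R")

#: Duration of one scoring epoch in seconds.
EPOCH_SECONDS = 30

#: Stage codes: 0 wake, 1 N1, 2 N2, 3 N3/N4 (merged), 4 REM.
STAGES = (0, 1, 2, 3, 4)
STAGE_NAMES = ("wake", "N1", "N2", "N3", "REM")


@dataclass
class ChannelMeta:
    """Per-channel acquisition metadata.

    Parameters
    ----------
    role : str
        One of :data:`ROLES`.
    sampling_rate : float
        Samples per second, > 0.
    physical_max : float
        Declared maximum physical acquisition amplitude in microvolts,
        as recorded in (and recovered from) the EDF header.  QC thresholds
        derive from this value.
    """

    role: str
    sampling_rate: float
    physical_max: float

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown channel role {self.role!r}; expected one of {ROLES}")
        if not self.sampling_rate > 0:
            raise ValueError("sampling rate must be > 0")
        if not self.physical_max > 0:
            raise ValueError("physical max amplitude must be > 0")


@dataclass
class PSGRecord:
    """One night of multi-channel signal data on a common 30 s epoch grid.

    ``channels`` maps role -> 1-D float array of samples in microvolts;
    ``meta`` maps role -> :class:`ChannelMeta`.  All channels must span the
    same total duration; a trailing partial epoch is truncated at load time.
    ``hypnogram`` optionally carries one stage label per epoch.
    """

    channels: dict[str, np.ndarray]
    meta: dict[str, ChannelMeta]
    hypnogram: np.ndarray | None = None

    def __post_init__(self) -> None:
        missing = [r for r in ROLES if r not in self.channels]
        if missing:
            raise ValueError(f"record is missing required channel roles: {missing}")
        durations = {r: len(x) / self.meta[r].sampling_rate for r, x in self.channels.items()}
        ref = next(iter(durations.values()))
        for r, d in durations.items():
            if abs(d - ref) > 1e-6:
                raise ValueError(f"channel {r} spans {d:.3f} s but others span {ref:.3f} s")
        if self.hypnogram is not None:
            self.hypnogram = np.asarray(self.hypnogram, dtype=int)
            if len(self.hypnogram) != self.n_epochs:
                raise ValueError(
                    f"hypnogram has {len(self.hypnogram)} labels for {self.n_epochs} epochs"
                )

    @property
    def duration(self) -> float:
        """Total duration in seconds (common to all channels)."""
        role = ROLES[0]
        return len(self.channels[role]) / self.meta[role].sampling_rate

    @property
    def n_epochs(self) -> int:
        return int(self.duration // EPOCH_SECONDS)

    def truncate_to_epoch_grid(self) -> "PSGRecord":
        """Drop any trailing partial epoch from every channel."""
        n_ep = self.n_epochs
        channels = {}
        for role, x in self.channels.items():
            spe = self.meta[role].sampling_rate * EPOCH_SECONDS
            n = int(round(spe * n_ep))
            channels[role] = x[:n]
        return PSGRecord(channels, dict(self.meta), self.hypnogram)

    def epoch(self, role: str, k: int) -> np.ndarray:
        """Samples of channel ``role`` in epoch ``k`` (half-open grid)."""
        if not 0 <= k < self.n_epochs:
            raise IndexError(f"epoch {k} outside night of {self.n_epochs} epochs")
        fs = self.meta[role].sampling_rate
        i0 = int(round(fs * EPOCH_SECONDS * k))
        i1 = int(round(fs * EPOCH_SECONDS * (k + 1)))
        return self.channels[role][i0:i1]


@dataclass
class QCReport:
    """Quality-control verdicts for one record.

    ``dropped_channels`` maps role -> whole-night mean absolute amplitude that
    triggered the drop.  ``excluded_epochs`` maps 0-based epoch index -> reason
    code in {"EEG-pair", "EOG-pair", "EMG", "record-level"}.
    """

    dropped_channels: dict[str, float] = field(default_factory=dict)
    excluded_epochs: dict[int, str] = field(default_factory=dict)

    @property
    def dropped_roles(self) -> set[str]:
        return set(self.dropped_channels)

    @property
    def excluded_indices(self) -> set[int]:
        return set(self.excluded_epochs)

    def retained_mask(self, n_epochs: int) -> np.ndarray:
        """Boolean mask over the night: True where the epoch survived QC."""
        mask = np.ones(n_epochs, dtype=bool)
        for k in self.excluded_epochs:
            if not 0 <= k < n_epochs:
                raise ValueError(f"excluded epoch {k} lies outside the night")
            mask[k] = False
        return mask

    def merge(self, other: "QCReport") -> "QCReport":
        dropped = dict(self.dropped_channels)
        for role, amp in other.dropped_channels.items():
            dropped.setdefault(role, amp)
        excluded = dict(self.excluded_epochs)
        excluded.update(other.excluded_epochs)
        return QCReport(dropped, excluded)

    def to_dict(self) -> dict:
        return {
            "dropped_channels": {r: float(a) for r, a in self.dropped_channels.items()},
            "excluded_epochs": {str(k): v for k, v in sorted(self.excluded_epochs.items())},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QCReport":
        return cls(
            {r: float(a) for r, a in d.get("dropped_channels", {}).items()},
            {int(k): v for k, v in d.get("excluded_epochs", {}).items()},
        )
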