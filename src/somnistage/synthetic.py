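"""Synthetic polysomnography with ground-truth hypnograms and injectable artifacts.

The generator emulates the stage-dependent spectral physiology a sleep-stage
classifier exploits: alpha rhythm and high muscle tone in wake, theta in N1,
theta plus spindle bursts in N2, high-amplitude slow delta in N3, and mixed
theta with muscle atonia and large slow eye movements in REM.  Stage sequences
come from a first-order Markov chain over the five classes; signals are
amplitude-modulated sinusoids plus Gaussian broadband noise, per channel role.

Three electrode-artifact kinds can be injected, mirroring the failure modes
seen in overnight recordings: a channel dropped for the whole night, a channel
dropped temporarily, and a recording left running after the electrodes were
removed in the morning.  Artifact epochs are overwritten with a constant
saturated amplitude on the specified channel only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .record import EPOCH_SECONDS, ROLES, STAGES, ChannelMeta, PSGRecord

#: Role-specific band-pass ranges (Hz) used downstream; template band centers
#: must lie inside their role's passband.
ROLE_PASSBANDS = {
    "C3": (0.3, 45.0),
    "C4": (0.3, 45.0),
    "EOG-L": (0.3, 12.0),
    "EOG-R": (0.3, 12.0),
    "EMG": (0.3, 20.0),
}

#: Default declared physical acquisition maximum per channel (microvolts).
DEFAULT_PHYSICAL_MAX = 250.0

#: Saturation artifacts default to 1.6x the declared physical maximum so that
#: both QC thresholds (half-max whole-night, full-max per-epoch) can fire even
#: on *filtered* data: the 51-tap band-pass cannot realize its 0.3 Hz high-pass
#: edge sharply, so a constant plateau keeps only ~75% of its amplitude after
#: the double pass, and a 1.2x plateau would slip under the per-epoch rule.
SATURATION_FACTOR = 1.6

ARTIFACT_KINDS = ("full-night-drop", "temporary-drop", "post-removal")


@dataclass
class Band:
    """One oscillation band: center frequency (Hz), bandwidth (Hz), amplitude (µV)."""

    center: float
    bandwidth: float
    amplitude: float


@dataclass
class TransientEvents:
    """Short oscillatory bursts (e.g. N2 sleep spindles) at a Poisson rate per epoch."""

    rate_per_epoch: float
    frequency: float
    duration: float  # seconds
    amplitude: float  # µV


@dataclass
class StageTemplate:
    """Spectral recipe for one sleep stage.

    ``bands`` maps channel role -> list of :class:`Band`; ``noise`` maps role ->
    Gaussian broadband noise standard deviation in µV; ``events`` maps role ->
    :class:`TransientEvents` for stages with phasic activity (N2 spindles).
    """

    stage: int
    bands: dict[str, list[Band]]
    noise: dict[str, float]
    events: dict[str, TransientEvents] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage}")
        any_positive = False
        for role, bands in self.bands.items():
            lo, hi = ROLE_PASSBANDS[role]
            for b in bands:
                if not lo <= b.center <= hi:
                    raise ValueError(
                        f"band center {b.center} Hz outside {role} passband {lo}-{hi} Hz"
                    )
                if b.amplitude < 0:
                    raise ValueError("band amplitudes must be nonnegative")
                any_positive = any_positive or b.amplitude > 0
        if not any_positive:
            raise ValueError("at least one band per template must have positive amplitude")


@dataclass
class HypnogramModel:
    """First-order Markov model of a night's stage sequence."""

    transition: np.ndarray
    initial: np.ndarray
    n_epochs: int

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        if self.transition.shape != (5, 5):
            raise ValueError("transition matrix must be 5x5")
        if np.any(self.transition < 0) or np.any(self.initial < 0):
            raise ValueError("probabilities must be nonnegative")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each transition-matrix row must sum to 1 (within 1e-9)")
        if not np.isclose(self.initial.sum(), 1.0, atol=1e-9):
            raise ValueError("initial distribution must sum to 1")
        if self.n_epochs < 1:
            raise ValueError("epochs per night must be >= 1")


@dataclass
class ArtifactSpec:
    """One injectable electrode artifact.

    ``epoch_range`` is half-open ``[start, end)`` on the 0-based epoch grid;
    a full-night-drop must cover every epoch of the night.  Affected epochs are
    overwritten with a constant signal at ``amplitude`` µV on ``role`` only.
    """

    kind: str
    role: str
    start_epoch: int
    end_epoch: int
    amplitude: float

    def __post_init__(self) -> None:
        if self.kind not in ARTIFACT_KINDS:
            raise ValueError(f"artifact kind must be one of {ARTIFACT_KINDS}")
        if self.role not in ROLES:
            raise ValueError(f"unknown channel role {self.role!r}")
        if self.start_epoch < 0 or self.end_epoch <= self.start_epoch:
            raise ValueError("epoch range must be nonempty and nonnegative")

    def validate_against_night(self, n_epochs: int) -> None:
        if self.end_epoch > n_epochs:
            raise ValueError(
                f"artifact epochs [{self.start_epoch}, {self.end_epoch}) exceed night of "
                f"{n_epochs} epochs"
            )
        if self.kind == "full-night-drop" and not (self.start_epoch == 0 and self.end_epoch == n_epochs):
            raise ValueError("full-night-drop must cover all epochs of the night")
        if self.kind == "post-removal" and self.end_epoch != n_epochs:
            raise ValueError("post-removal artifacts must extend to the end of the night")


def default_templates() -> dict[int, StageTemplate]:
    """Stage templates encoding textbook AASM spectral physiology.

    Amplitudes are in µV and sit well inside a 250 µV acquisition range, so a
    clean night never trips the QC thresholds.  EMG muscle tone is encoded as
    a 10-20 Hz band whose amplitude falls from wake through N3 to REM atonia;
    REM carries large slow EOG deflections.
    """
    eeg = ("C3", "C4")
    eog = ("EOG-L", "EOG-R")

    def mk(stage, eeg_bands, eog_bands, emg_amp, events=None):
        bands: dict[str, list[Band]] = {}
        noise = {}
        for r in eeg:
            bands[r] = [Band(*b) for b in eeg_bands]
            noise[r] = 8.0
        for r in eog:
            bands[r] = [Band(*b) for b in eog_bands]
            noise[r] = 8.0
        bands["EMG"] = [Band(15.0, 8.0, emg_amp)] if emg_amp > 0 else [Band(15.0, 8.0, 0.0)]
        if emg_amp == 0:
            bands["EMG"] = [Band(10.0, 6.0, 1.0)]  # residual tone so invariants hold
        noise["EMG"] = 5.0
        ev = {}
        if events:
            for r in eeg:
                ev[r] = events
        return StageTemplate(stage, bands, noise, ev)

    return {
        # wake: posterior alpha, small eye activity, high muscle tone
        0: mk(0, [(10.0, 2.5, 30.0)], [(0.8, 0.8, 15.0)], 25.0),
        # N1: low-amplitude theta, slow rolling eye movements, reduced tone
        1: mk(1, [(5.5, 2.5, 25.0)], [(0.6, 0.6, 20.0)], 12.0),
        # N2: theta background plus 12-14 Hz spindle bursts (~3 per epoch)
        2: mk(
            2,
            [(5.5, 2.5, 25.0)],
            [(0.6, 0.6, 10.0)],
            8.0,
            events=TransientEvents(rate_per_epoch=3.0, frequency=13.0, duration=1.0, amplitude=30.0),
        ),
        # N3: high-amplitude slow delta dominating the EEG
        3: mk(3, [(1.2, 1.0, 60.0)], [(1.2, 1.0, 20.0)], 5.0),
        # REM: mixed theta, large slow EOG deflections, muscle atonia
        4: mk(4, [(5.5, 2.5, 22.0)], [(0.7, 0.6, 60.0)], 0.0),
    }


def default_hypnogram_model(n_epochs: int = 960) -> HypnogramModel:
    """Plausible overnight stage architecture (sticky stages, wake onset)."""
    transition = np.array(
        [
            [0.88, 0.10, 0.01, 0.00, 0.01],  # wake
            [0.10, 0.60, 0.28, 0.00, 0.02],  # N1
            [0.02, 0.05, 0.80, 0.10, 0.03],  # N2
            [0.01, 0.01, 0.13, 0.84, 0.01],  # N3
            [0.05, 0.05, 0.05, 0.00, 0.85],  # REM
        ]
    )
    initial = np.array([0.9, 0.1, 0.0, 0.0, 0.0])
    return HypnogramModel(transition, initial, n_epochs)


def generate_hypnogram(model: HypnogramModel, seed: int) -> np.ndarray:
    """Draw one night's stage sequence from the Markov model.

    Identical ``(model, seed)`` give a bit-identical sequence.
    """
    rng = np.random.default_rng(seed)
    labels = np.empty(model.n_epochs, dtype=int)
    labels[0] = rng.choice(5, p=model.initial)
    for k in range(1, model.n_epochs):
        labels[k] = rng.choice(5, p=model.transition[labels[k - 1]])
    return labels


def _band_signal(band: Band, t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Amplitude-modulated sinusoid within the band, frequency re-drawn per epoch."""
    f = rng.uniform(band.center - band.bandwidth / 2, band.center + band.bandwidth / 2)
    f = max(f, 0.1)
    phase = rng.uniform(0, 2 * np.pi)
    mod_f = rng.uniform(0.1, 0.4)
    mod_phase = rng.uniform(0, 2 * np.pi)
    envelope = 1.0 + 0.25 * np.sin(2 * np.pi * mod_f * t + mod_phase)
    return band.amplitude * envelope * np.sin(2 * np.pi * f * t + phase)


def _event_signal(
    ev: TransientEvents, t: np.ndarray, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Poisson-placed oscillatory bursts with a Hann envelope (spindles)."""
    out = np.zeros_like(t)
    n_events = rng.poisson(ev.rate_per_epoch)
    n_burst = int(round(ev.duration * fs))
    if n_burst < 2:
        return out
    window = np.hanning(n_burst)
    for _ in range(n_events):
        start = rng.integers(0, max(1, len(t) - n_burst))
        tt = t[start : start + n_burst]
        phase = rng.uniform(0, 2 * np.pi)
        out[start : start + n_burst] += (
            ev.amplitude * window[: len(tt)] * np.sin(2 * np.pi * ev.frequency * tt + phase)
        )
    return out


def synthesize_record(
    hypnogram: np.ndarray,
    templates: dict[int, StageTemplate] | None = None,
    artifacts: list[ArtifactSpec] | None = None,
    sampling_rate: float = 125.0,
    seed: int = 0,
    physical_max: float = DEFAULT_PHYSICAL_MAX,
) -> PSGRecord:
    """Render a hypnogram into a five-channel record, then inject artifacts.

    Parameters
    ----------
    hypnogram : array of int
        Stage label (0-4) per 30 s epoch.
    templates : dict stage -> StageTemplate
        One template per stage present in the hypnogram (defaults to
        :func:`default_templates`).
    artifacts : list of ArtifactSpec
        Saturation artifacts, applied after clean synthesis; each overwrites
        only its channel/epoch range.
    sampling_rate : float
        Acquisition rate in Hz, >= 100.
    physical_max : float
        Declared acquisition maximum written into channel metadata.
    """
    hypnogram = np.asarray(hypnogram, dtype=int)
    if templates is None:
        templates = default_templates()
    if sampling_rate < 100:
        raise ValueError("sampling rate must be >= 100 Hz")
    present = set(int(s) for s in np.unique(hypnogram))
    missing = present - set(templates)
    if missing:
        raise ValueError(f"no template for stages {sorted(missing)} present in hypnogram")

    rng = np.random.default_rng(seed)
    n_epochs = len(hypnogram)
    spe = int(round(sampling_rate * EPOCH_SECONDS))
    t_epoch = np.arange(spe) / sampling_rate

    channels = {r: np.zeros(n_epochs * spe) for r in ROLES}
    for k, stage in enumerate(hypnogram):
        tpl = templates[int(stage)]
        sl = slice(k * spe, (k + 1) * spe)
        for role in ROLES:
            x = np.zeros(spe)
            for band in tpl.bands.get(role, []):
                if band.amplitude > 0:
                    x += _band_signal(band, t_epoch, rng)
            if role in tpl.events:
                x += _event_signal(tpl.events[role], t_epoch, sampling_rate, rng)
            sigma = tpl.noise.get(role, 0.0)
            if sigma > 0:
                x += rng.normal(0.0, sigma, spe)
            channels[role][sl] = x

    for art in artifacts or []:
        art.validate_against_night(n_epochs)
        channels[art.role][art.start_epoch * spe : art.end_epoch * spe] = art.amplitude

    meta = {r: ChannelMeta(r, sampling_rate, physical_max) for r in ROLES}
    return PSGRecord(channels, meta, hypnogram)


# ---------------------------------------------------------------------------
# hypnogram CSV and config-file plumbing

def write_hypnogram(labels: np.ndarray, path) -> None:
    """Write a two-column CSV: 0-based epoch index, stage label 0-4."""
    pd.DataFrame({"epoch": np.arange(len(labels)), "stage": np.asarray(labels, dtype=int)}).to_csv(
        path, index=False
    )


def read_hypnogram(path) -> np.ndarray:
    df = pd.read_csv(path)
    if not {"epoch", "stage"}.issubset(df.columns):
        raise ValueError("hypnogram CSV must have 'epoch' and 'stage' columns")
    df = df.sort_values("epoch")
    if not np.array_equal(df["epoch"].to_numpy(), np.arange(len(df))):
        raise ValueError("hypnogram epochs must be contiguous from 0")
    return df["stage"].to_numpy(dtype=int)


def parse_artifact_arg(text: str, n_epochs: int) -> ArtifactSpec:
    """Parse a CLI artifact spec ``kind:role:start:end[:amplitude]``."""
    parts = text.split(":")
    if len(parts) not in (4, 5):
        raise ValueError("artifact spec must be kind:role:start:end[:amplitude]")
    kind, role, start, end = parts[:4]
    amp = float(parts[4]) if len(parts) == 5 else SATURATION_FACTOR * DEFAULT_PHYSICAL_MAX
    if kind == "full-night-drop":
        start, end = 0, n_epochs
    return ArtifactSpec(kind, role, int(start), int(end), amp)


def artifacts_from_config(path, n_epochs: int) -> list[ArtifactSpec]:
    """Load artifact specs from a YAML/JSON file.

    Expected layout::

        artifacts:
          - kind: temporary-drop
            role: C3
            start_epoch: 10
            end_epoch: 13
            amplitude: 300.0
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    out = []
    for item in cfg.get("artifacts", []):
        spec = ArtifactSpec(
            item["kind"],
            item["role"],
            int(item.get("start_epoch", 0)),
            int(item.get("end_epoch", n_epochs)),
            float(item.get("amplitude", SATURATION_FACTOR * DEFAULT_PHYSICAL_MAX)),
        )
        spec.validate_against_night(n_epochs)
        out.append(spec)
    return out
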