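"""ECG ingest, segmentation into 5-minute epochs, and Z-score normalization.

Also provides a deterministic synthetic-record generator so the package is
fully buildable and testable without downloading Holter recordings.  The
generator emits multi-channel pulse-train ECG-like waveforms (Gaussian-
derivative QRS complexes plus a T-wave bump at a configurable heart rate)
with additive AR(1) colored noise.  It reproduces the *plumbing* of the
target data -- 128 Hz, three channels, long-duration records -- and makes
no claim of class-discriminating hypertensive morphology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import lfilter

logger = logging.getLogger(__name__)

__all__ = [
    "ECGRecord",
    "Epoch",
    "ZeroVarianceError",
    "segment",
    "zscore",
    "synthesize_record",
]

CLASS_LABELS = ("LRHT", "HRHT", "unknown")
HRHT_SUBTYPES = ("myocardial_infarction", "stroke", "syncope")


class ZeroVarianceError(ValueError):
    """A flatline epoch cannot be Z-score normalized."""


@dataclass
class ECGRecord:
    """A multi-channel ECG recording.

    Channels are named arrays; for Holter data following the convention
    used here, CH1 = lead III, CH2 = V3, CH3 = V5.
    """

    channels: dict[str, np.ndarray]
    fs: float
    subject_id: str = ""
    class_label: str = "unknown"
    hrht_subtype: str | None = None

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")
        lengths = {name: len(sig) for name, sig in self.channels.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"channels differ in length: {lengths}")
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"class_label must be one of {CLASS_LABELS}")
        if self.hrht_subtype is not None and self.hrht_subtype not in HRHT_SUBTYPES:
            raise ValueError(f"hrht_subtype must be one of {HRHT_SUBTYPES}")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))


@dataclass
class Epoch:
    """One fixed-duration window of one channel."""

    samples: np.ndarray
    fs: float
    subject_id: str
    channel: str
    class_label: str
    epoch_index: int = 0
    duration_s: float = 300.0

    @property
    def epoch_id(self) -> str:
        return f"{self.subject_id}/{self.channel}/{self.epoch_index}"


def segment(record: ECGRecord, epoch_s: float = 300.0) -> list[Epoch]:
    """Cut a record into consecutive non-overlapping epochs.

    The window is ``round(epoch_s * fs)`` samples; a trailing partial
    window is discarded, so each channel yields
    ``floor(n_samples / window)`` epochs.
    """
    window = round(epoch_s * record.fs)
    epochs: list[Epoch] = []
    n = record.n_samples
    if n < window:
        logger.warning(
            "record %s (%d samples) shorter than one %d-sample epoch; "
            "returning no epochs",
            record.subject_id, n, window,
        )
        return epochs
    count = n // window
    for channel, sig in record.channels.items():
        for i in range(count):
            epochs.append(
                Epoch(
                    samples=sig[i * window:(i + 1) * window],
                    fs=record.fs,
                    subject_id=record.subject_id,
                    channel=channel,
                    class_label=record.class_label,
                    epoch_index=i,
                    duration_s=epoch_s,
                )
            )
    return epochs


def zscore(epoch: Epoch) -> Epoch:
    """Z-score normalize an epoch using the population standard deviation.

    Output has mean 0 and standard deviation 1 (1/n convention).  A
    zero-variance (flatline) epoch raises :class:`ZeroVarianceError`.
    """
    x = np.asarray(epoch.samples, dtype=float)
    sd = float(x.std())
    if sd == 0.0 or np.ptp(x) == 0.0:
        raise ZeroVarianceError(
            f"epoch {epoch.epoch_id} has zero variance (flatline channel)"
        )
    return replace(epoch, samples=(x - x.mean()) / sd)


# --------------------------------------------------------------------------
# synthetic records
# --------------------------------------------------------------------------

# relative per-channel scaling of the synthetic leads; arbitrary but fixed
_CHANNEL_GAINS = {"CH1": 0.6, "CH2": 1.0, "CH3": 0.8}


def _beat_template(fs: float) -> np.ndarray:
    """One QRS-like complex (Gaussian derivative) plus a T-wave bump."""
    t = np.arange(int(0.6 * fs)) / fs - 0.15
    qrs_sigma = 0.012
    qrs = -(t / qrs_sigma) * np.exp(-(t**2) / (2 * qrs_sigma**2))
    t_wave = 0.25 * np.exp(-((t - 0.25) ** 2) / (2 * 0.05**2))
    return qrs + t_wave


def synthesize_record(
    class_label: str = "LRHT",
    fs: float = 128.0,
    duration_s: float = 7812.0,
    heart_rate_bpm: float = 60.0,
    noise_sd: float = 0.1,
    seed: int = 0,
    subject_id: str | None = None,
    hrht_subtype: str | None = None,
) -> ECGRecord:
    """Deterministic three-channel synthetic ECG-like record.

    A strictly periodic pulse train of QRS-like complexes at
    ``heart_rate_bpm`` plus AR(1) colored noise (coefficient 0.9, standard
    deviation ``noise_sd``), independently drawn per channel.  With
    ``noise_sd = 0`` and an integer beat interval the output is exactly
    periodic.  Default duration is 2 h 10 min 12 s, matching long Holter
    records.  The class label is carried through for downstream labeling
    only; the waveform morphology does not encode it.
    """
    if duration_s < 300:
        raise ValueError("duration_s must be at least 300 (one epoch)")
    if heart_rate_bpm <= 0:
        raise ValueError("heart_rate_bpm must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if class_label not in CLASS_LABELS:
        raise ValueError(f"class_label must be one of {CLASS_LABELS}")

    rng = np.random.default_rng(seed)
    n = round(duration_s * fs)
    interval = fs * 60.0 / heart_rate_bpm
    template = _beat_template(fs)

    pulse = np.zeros(n)
    starts = np.round(np.arange(0.0, n, interval)).astype(np.int64)
    offsets = np.arange(len(template))
    idx = (starts[:, None] + offsets[None, :]).ravel()
    vals = np.broadcast_to(template, (len(starts), len(template))).ravel()
    keep = idx < n
    np.add.at(pulse, idx[keep], vals[keep])

    channels: dict[str, np.ndarray] = {}
    for name, gain in _CHANNEL_GAINS.items():
        sig = gain * pulse
        if noise_sd > 0:
            white = rng.standard_normal(n)
            ar = lfilter([1.0], [1.0, -0.9], white)
            ar *= noise_sd / np.sqrt(1.0 / (1.0 - 0.9**2))
            sig = sig + ar
        channels[name] = sig

    if subject_id is None:
        subject_id = f"synthetic-{class_label}-{seed}"
    return ECGRecord(
        channels=channels,
        fs=fs,
        subject_id=subject_id,
        class_label=class_label,
        hrht_subtype=hrht_subtype,
    )
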