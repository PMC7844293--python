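"""EEG preprocessing: filtering, re-referencing, epoch trimming and the
blink-component rejection rule.

The pipeline applied to each epoch mirrors the recording analysis: a 25 Hz
sixth-order Butterworth low-pass applied forward and backward (zero net
phase, which matters because the downstream measure is phase coherence),
common-average re-referencing, and removal of the first four words (1.28 s)
of each stream so that the analysed epoch is exactly 15.36 s.  ICA itself is
out of scope: only the frontal-power rejection rule that decides whether a
computed component topography is an eyeblink is implemented.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .design import FS_HZ, WORD_MS, WORDS_DROPPED, WORDS_PER_STREAM
from .errors import InvalidInputError

#: 10-20 electrode names treated as "the most frontal four channels".
FRONTAL_LABELS: frozenset[str] = frozenset({"Fp1", "Fp2", "F7", "F8"})


@dataclass
class EEGEpoch:
    """A channels x samples epoch with sampling rate and trim state."""

    data: np.ndarray
    fs: float = FS_HZ
    trimmed: bool = False
    channel_labels: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidInputError("epoch data must be channels x samples")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:02d}" for i in range(self.data.shape[0])]
        if len(self.channel_labels) != self.data.shape[0]:
            raise InvalidInputError("one label per channel required")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class ComponentTopography:
    """Channel weights of one ICA component, for blink screening."""

    weights: np.ndarray
    channel_labels: list[str]
    frontal_labels: frozenset[str] = FRONTAL_LABELS

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.channel_labels),):
            raise InvalidInputError("one weight per channel required")


def lowpass_filter(epoch: EEGEpoch, cutoff_hz: float = 25.0, order: int = 6) -> EEGEpoch:
    """Zero-phase Butterworth low-pass (applied forward and backward).

    DC gain is 1 and the net phase response is zero, so tag-frequency phases
    are untouched in the passband.
    """
    if not 0 < cutoff_hz < epoch.fs / 2:
        raise InvalidInputError(
            f"cutoff {cutoff_hz} Hz must be below the Nyquist frequency {epoch.fs / 2} Hz"
        )
    sos = sps.butter(order, cutoff_hz, btype="low", fs=epoch.fs, output="sos")
    data = sps.sosfiltfilt(sos, epoch.data, axis=-1)
    return replace(epoch, data=data, meta=dict(epoch.meta))


def common_average_reference(epoch: EEGEpoch) -> EEGEpoch:
    """Subtract the instantaneous mean over channels from every channel."""
    if epoch.n_channels < 2:
        raise InvalidInputError("common average reference needs at least 2 channels")
    data = epoch.data - epoch.data.mean(axis=0, keepdims=True)
    return replace(epoch, data=data, meta=dict(epoch.meta))


def blink_component_rejection(topography: ComponentTopography, ratio: float = 10.0) -> bool:
    """Eyeblink rule: reject a component iff the mean power (squared weight)
    over the four frontal channels strictly exceeds ``ratio`` times the mean
    power over all other channels."""
    labels = topography.channel_labels
    if len(labels) < 5:
        raise InvalidInputError("need at least 5 channels to apply the frontal rule")
    frontal = [i for i, l in enumerate(labels) if l in topography.frontal_labels]
    if len(frontal) != len(topography.frontal_labels):
        missing = topography.frontal_labels - set(labels)
        raise InvalidInputError(f"missing frontal channels: {sorted(missing)}")
    other = [i for i in range(len(labels)) if i not in frontal]
    power = topography.weights**2
    return bool(power[frontal].mean() > ratio * power[other].mean())


def epoch_and_trim(
    epoch: EEGEpoch,
    word_ms: int = WORD_MS,
    words_dropped: int = WORDS_DROPPED,
    n_words: int = WORDS_PER_STREAM,
) -> EEGEpoch:
    """Drop the onset-transient words and keep exactly the analysed window.

    With the defaults this removes the first 1.28 s (4 words) and keeps
    48 x 0.32 s = 15.36 s, i.e. 15360 samples at 1 kHz.
    """
    if epoch.trimmed:
        raise InvalidInputError("epoch is already trimmed")
    drop = round(words_dropped * word_ms * epoch.fs / 1000.0)
    keep = round((n_words - words_dropped) * word_ms * epoch.fs / 1000.0)
    if epoch.n_samples < drop + keep:
        raise InvalidInputError(
            f"epoch has {epoch.n_samples} samples, need at least {drop + keep}"
        )
    data = epoch.data[:, drop : drop + keep]
    return replace(epoch, data=data, trimmed=True, meta=dict(epoch.meta))
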