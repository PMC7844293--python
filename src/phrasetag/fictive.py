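"""Fictive EEG: simulated multichannel signals built from word embeddings.

Each word's embedding vector is tiled over its 320 ms presentation window,
gated by a per-word onset delay tau drawn uniformly on an integer-ms
interval, and summed with unit-variance pink (1/f) noise scaled by eta.
Component e of the voltage during word i is::

    v_e(t) = eta * xi_e(t)            t < tau_i   (within the word window)
    v_e(t) = w_e^i + eta * xi_e(t)    t >= tau_i

with an independent tau per word and one continuous noise stream xi_e per
component per stream.  A simulated participant is a random subset of 32
"electrodes" from the embedding components plus fresh noise instances; this
lends the output the look of multi-participant data without modelling true
between-participant variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .design import FS_HZ, WORD_MS
from .errors import InvalidInputError
from .preprocess import EEGEpoch
from .streams import Condition, Stream


@dataclass(frozen=True)
class FictiveEEGParams:
    """Simulation parameters; defaults are the study's configuration."""

    eta: float = 0.5                      # noise amplitude (dimensionless)
    tau_range: tuple[int, int] = (20, 60)  # onset delay interval, ms, inclusive
    word_ms: int = WORD_MS
    dt_ms: int = 1
    n_components: int = 300
    n_electrodes: int = 32
    n_participants: int = 20

    def __post_init__(self):
        if self.eta < 0:
            raise InvalidInputError("eta must be nonnegative")
        lo, hi = self.tau_range
        if not (0 <= lo <= hi < self.word_ms):
            raise InvalidInputError(f"tau_range {self.tau_range} must lie within [0, {self.word_ms})")
        if self.n_electrodes > self.n_components:
            raise InvalidInputError("cannot sample more electrodes than components")


@dataclass
class FictiveTrial:
    """Simulated signal for one stream: components x milliseconds."""

    signal: np.ndarray
    stream_id: str
    delays: np.ndarray                      # per-word tau, ms
    component_indices: np.ndarray | None = None  # None = all components


def _pink(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """Rows of standardised pink noise via 1/sqrt(f) spectral shaping."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    k = np.arange(spec.shape[-1], dtype=float)
    k[0] = 1.0
    spec /= np.sqrt(k)
    spec[..., 0] = 0.0  # zero DC -> exact zero mean
    x = np.fft.irfft(spec, n=n, axis=-1)
    x /= x.std(axis=-1, keepdims=True)
    return x


def pink_noise(n: int, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Length-``n`` pink-noise sequence with zero mean and unit variance.

    The amplitude spectrum is shaped proportional to 1/sqrt(f) (power
    spectral density 1/f), the DC component is removed, and the output is
    standardised to exactly unit sample variance.
    """
    if n < 2:
        raise InvalidInputError("pink noise needs n >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _pink(rng, (n,))


def fictive_stream_signal(
    stream_vectors: np.ndarray,
    params: FictiveEEGParams = FictiveEEGParams(),
    seed: int | np.random.Generator = 0,
    component_indices: np.ndarray | None = None,
    taus: np.ndarray | None = None,
    stream_id: str = "",
) -> FictiveTrial:
    """Simulate one stream's fictive signal from its (n_words, dim) vectors.

    ``component_indices`` restricts generation to a subset of embedding
    components (rows); because the noise is independent across components
    this is identical to simulating all of them and subsetting.  ``taus``
    overrides the random per-word delays (useful for noise-free checks).
    RNG draw order is: delays first, then noise.
    """
    W = np.asarray(stream_vectors, dtype=float)
    if W.ndim != 2:
        raise InvalidInputError("stream_vectors must be (n_words, dim)")
    n_words, dim = W.shape
    if dim != params.n_components:
        raise InvalidInputError(
            f"stream vectors have dimension {dim}, params expect {params.n_components}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = params.tau_range
    if taus is None:
        taus = rng.integers(lo, hi + 1, size=n_words)  # inclusive interval
    else:
        taus = np.asarray(taus, dtype=int)
        if taus.shape != (n_words,):
            raise InvalidInputError(f"taus must have shape ({n_words},)")
    if component_indices is not None:
        W = W[:, np.asarray(component_indices)]
    d = W.shape[1]
    word_ms = params.word_ms
    # word part: embedding tiled over the word window, zeroed before tau
    gate = (np.arange(word_ms)[None, :] >= taus[:, None]).astype(float)  # (words, word_ms)
    word_part = (W.T[:, :, None] * gate[None, :, :]).reshape(d, n_words * word_ms)
    if params.eta > 0:
        signal = word_part + params.eta * _pink(rng, (d, n_words * word_ms))
    else:
        signal = word_part
    return FictiveTrial(signal, stream_id, taus, component_indices)


def simulate_participant(
    streams: list[Stream],
    params: FictiveEEGParams = FictiveEEGParams(),
    participant_seed: int = 0,
    participant_id: str = "p0",
    electrode_indices: np.ndarray | None = None,
) -> list[EEGEpoch]:
    """Simulate one participant's epochs for a list of streams.

    A participant is a single random draw of ``n_electrodes`` distinct
    component indices (reused for every stream) plus fresh noise and onset
    delays per stream.
    """
    ss = np.random.SeedSequence(participant_seed)
    rng_elec, rng_trials = [np.random.default_rng(s) for s in ss.spawn(2)]
    if electrode_indices is None:
        electrode_indices = np.sort(
            rng_elec.choice(params.n_components, size=params.n_electrodes, replace=False)
        )
    else:
        electrode_indices = np.asarray(electrode_indices)
        if len(np.unique(electrode_indices)) != len(electrode_indices):
            raise InvalidInputError("electrode indices must be distinct")
    labels = [f"c{int(i):03d}" for i in electrode_indices]
    epochs = []
    for stream in streams:
        trial = fictive_stream_signal(
            stream.vectors(),
            params,
            seed=rng_trials,
            component_indices=electrode_indices,
            stream_id=stream.stream_id,
        )
        epochs.append(
            EEGEpoch(
                data=trial.signal,
                fs=FS_HZ * params.dt_ms,
                trimmed=False,
                channel_labels=labels,
                meta={
                    "participant": participant_id,
                    "condition": stream.condition.value,
                    "stream_id": stream.stream_id,
                    "electrode_indices": [int(i) for i in electrode_indices],
                },
            )
        )
    return epochs


def shuffle_stream(stream: Stream, seed: int = 0) -> Stream:
    """Uniformly random permutation of a stream's tokens (the simulator's
    fully random reference condition, relabelled SHUF)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(stream.tokens))
    tokens = [stream.tokens[i] for i in perm]
    return Stream(tokens, Condition.SHUF, f"{stream.stream_id}-shuf")
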