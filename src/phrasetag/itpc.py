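"""Inter-trial phase coherence (ITPC) from DFT phase spectra.

ITPC — the mean resultant length of circular statistics — measures phase
clustering across trials at one frequency:

    R = | sum_k exp(i * theta_k) | / K

where theta_k is the phase of the DFT coefficient for trial k and K the
trial count.  R = 1 means identical phase on every trial; for uniformly
random phases R concentrates near (1/2) sqrt(pi / K).

Frequencies are addressed by DFT bin index of the 15.36 s analysed epoch
(bin spacing 1/15.36 ~ 0.0651 Hz); Hz values are presentation only, which
keeps requests exactly bin-centred.  Two grouping modes are provided:
per participant x condition (trials = streams, the primary analysis) and
per item (trials = participants).  Both average the per-electrode R over
electrodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .design import analysed_duration_s
from .errors import InvalidInputError
from .preprocess import EEGEpoch


@dataclass
class PhaseSet:
    """Phase angles of one frequency across trials, for one channel."""

    phases: np.ndarray
    f: float | None = None

    def __post_init__(self):
        self.phases = np.mod(np.asarray(self.phases, dtype=float), 2 * np.pi)

    @property
    def K(self) -> int:
        return len(self.phases)


@dataclass
class PhaseRecord:
    """DFT phases for one epoch: (channels, bins), with grouping labels."""

    participant: str
    condition: str
    stream_id: str
    phases: np.ndarray  # (n_channels, n_bins)


@dataclass
class ITPCSpectrum:
    """Tidy ITPC table plus its grouping mode.

    ``table`` columns: the grouping keys, ``bin``, ``freq_hz``, ``itpc``.
    """

    table: pd.DataFrame
    grouping: str
    bins: np.ndarray

    @property
    def freqs(self) -> np.ndarray:
        return self.bins / analysed_duration_s()


def freq_to_bin(freq_hz: float, duration_s: float | None = None, tol: float = 1e-9) -> int:
    """Map a frequency to its exact DFT bin index, or fail naming the nearest.

    Requests must sit on a bin centre (k / duration); off-bin requests are
    errors rather than silently snapped, since leakage would bias phase.
    """
    duration_s = analysed_duration_s() if duration_s is None else duration_s
    k = freq_hz * duration_s
    k_round = round(k)
    if abs(k - k_round) > tol * max(1.0, abs(k)):
        raise InvalidInputError(
            f"{freq_hz} Hz is not a DFT bin centre; nearest bin is {k_round} "
            f"({k_round / duration_s:.6f} Hz)"
        )
    return int(k_round)


def dft_phases(epoch: EEGEpoch, bins: Sequence[int] | None = None,
               freqs: Sequence[float] | None = None) -> np.ndarray:
    """Phases of the DFT coefficients at the requested bins, per channel.

    Rectangular window, no zero-padding, no detrending.  Returns an array of
    shape (n_channels, n_bins) with the complex argument of each coefficient
    (cosine convention: a pure cosine at a bin frequency has phase 0).
    """
    if not epoch.trimmed:
        raise InvalidInputError("epoch must be trimmed before spectral analysis")
    duration = epoch.n_samples / epoch.fs
    if bins is None:
        if freqs is None:
            raise InvalidInputError("specify bins or freqs")
        bins = [freq_to_bin(f, duration) for f in freqs]
    bins = np.asarray(bins, dtype=int)
    n_rfft_bins = epoch.n_samples // 2 + 1
    if np.any(bins < 0) or np.any(bins >= n_rfft_bins):
        raise InvalidInputError(f"bins must lie in [0, {n_rfft_bins - 1}]")
    spectrum = np.fft.rfft(epoch.data, axis=-1)
    return np.angle(spectrum[:, bins])


def itpc_from_phases(phase_set: PhaseSet | np.ndarray) -> float:
    """Mean resultant length R of a set of phases; in [0, 1]."""
    phases = phase_set.phases if isinstance(phase_set, PhaseSet) else np.asarray(phase_set, float)
    if phases.size == 0:
        raise InvalidInputError("empty phase set")
    return float(np.abs(np.exp(1j * phases).sum()) / phases.size)


def itpc_over_trials(phases: np.ndarray, axis: int = 0) -> np.ndarray:
    """Vectorised R along ``axis`` (trial axis) of a phase array."""
    phases = np.asarray(phases, dtype=float)
    if phases.shape[axis] == 0:
        raise InvalidInputError("empty trial axis")
    return np.abs(np.exp(1j * phases).mean(axis=axis))


def itpc_squared_unbiased(phases: np.ndarray, axis: int = 0) -> np.ndarray:
    """Bias-corrected squared ITPC, (K R^2 - 1) / (K - 1).

    The raw R over K trials is biased upward (E[R] > 0 for uniform phases);
    this estimator's expectation is exactly the squared population mean
    resultant length, making small-K locking-strength recovery comparable
    against analytic values.
    """
    phases = np.asarray(phases, dtype=float)
    K = phases.shape[axis]
    if K < 2:
        raise InvalidInputError("bias correction needs at least 2 trials")
    R = itpc_over_trials(phases, axis=axis)
    return (K * R**2 - 1.0) / (K - 1.0)


def phases_from_epochs(epochs: Iterable[EEGEpoch], bins: Sequence[int]) -> list[PhaseRecord]:
    """Convert epochs to compact phase records at the requested bins."""
    records = []
    for ep in epochs:
        records.append(
            PhaseRecord(
                participant=str(ep.meta.get("participant", "")),
                condition=str(ep.meta.get("condition", "")),
                stream_id=str(ep.meta.get("stream_id", "")),
                phases=dft_phases(ep, bins=bins),
            )
        )
    return records


def _coerce_records(data, bins) -> list[PhaseRecord]:
    data = list(data)
    if data and isinstance(data[0], EEGEpoch):
        return phases_from_epochs(data, bins)
    return data


def _grouped_itpc(records: list[PhaseRecord], bins, key_fn, trial_name, keys_out,
                  grouping: str) -> ITPCSpectrum:
    bins = np.asarray(bins, dtype=int)
    groups: dict[tuple, list[PhaseRecord]] = {}
    for r in records:
        groups.setdefault(key_fn(r), []).append(r)
    rows = []
    duration = analysed_duration_s()
    for key in sorted(groups):
        recs = groups[key]
        if len(recs) < 2:
            raise InvalidInputError(
                f"grouping cell {dict(zip(keys_out, key))} has {len(recs)} {trial_name}; need >= 2"
            )
        shapes = {r.phases.shape for r in recs}
        if len(shapes) > 1:
            raise InvalidInputError(f"inconsistent channel/bin shapes in cell {key}: {shapes}")
        stacked = np.stack([r.phases for r in recs])      # (K, channels, bins)
        r_elec = itpc_over_trials(stacked, axis=0)        # (channels, bins)
        r_avg = r_elec.mean(axis=0)                       # electrode average
        for b, val in zip(bins, r_avg):
            rows.append((*key, int(b), b / duration, float(val)))
    table = pd.DataFrame(rows, columns=[*keys_out, "bin", "freq_hz", "itpc"])
    return ITPCSpectrum(table=table, grouping=grouping, bins=bins)


def itpc_by_participant_condition(data, bins: Sequence[int]) -> ITPCSpectrum:
    """R(f; p, c): trials are the streams of one condition for one
    participant; the per-electrode R is then averaged over electrodes.

    ``data`` may be EEGEpoch objects (phases are computed here) or
    precomputed PhaseRecord objects.
    """
    records = _coerce_records(data, bins)
    return _grouped_itpc(
        records, bins,
        key_fn=lambda r: (r.participant, r.condition),
        trial_name="streams", keys_out=("participant", "condition"),
        grouping="participant x condition",
    )


def itpc_by_item(data, bins: Sequence[int]) -> ITPCSpectrum:
    """R(f; s, c): the per-item analysis, with participants as trials."""
    records = _coerce_records(data, bins)
    return _grouped_itpc(
        records, bins,
        key_fn=lambda r: (r.stream_id, r.condition),
        trial_name="participants", keys_out=("stream_id", "condition"),
        grouping="stream x condition",
    )


def grand_average(spectrum: ITPCSpectrum) -> pd.DataFrame:
    """Average the grouped ITPC over the first grouping key (per condition)."""
    return (
        spectrum.table.groupby(["condition", "bin", "freq_hz"], as_index=False)["itpc"]
        .mean()
        .sort_values(["condition", "bin"], ignore_index=True)
    )
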