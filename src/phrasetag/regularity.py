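"""Alternating-sign Fourier regularity statistic of a word stream.

For stream word vectors w^i (i = 0..n-1) the statistic is

    phi = sum_e | sum_i (-1)^i w_e^i |

i.e. the magnitude, summed over embedding components, of the stream's
Fourier coefficient at the two-word alternation frequency.  A stream that
strictly alternates between two regions of embedding space has a large phi;
a shuffled stream's alternating sums random-walk toward zero.  Condition
means are reported normalised to the shuffled reference condition, whose
normalised value is 1 by construction.  phi is a stimulus-regularity
diagnostic only; it makes no claim about recorded ITPCs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError


@dataclass
class RegularityScore:
    """Normalised condition-level phi values."""

    condition_means: dict[str, float]
    reference: str
    normalized: dict[str, float]


def phi_statistic(stream_vectors: np.ndarray) -> float:
    """phi of an ordered (n_words, dim) vector matrix; index origin 0."""
    V = np.asarray(stream_vectors, dtype=float)
    if V.ndim != 2 or V.shape[0] < 2:
        raise InvalidInputError("need >= 2 vectors of equal dimension, shape (n_words, dim)")
    signs = np.where(np.arange(V.shape[0]) % 2 == 0, 1.0, -1.0)
    return float(np.abs((signs[:, None] * V).sum(axis=0)).sum())


def normalized_condition_phi(
    scores_by_condition: dict[str, list[float] | np.ndarray],
    reference: str,
) -> RegularityScore:
    """Per-condition mean phi divided by the reference (shuffled) mean."""
    if reference not in scores_by_condition:
        raise InvalidInputError(f"reference condition {reference!r} missing")
    means = {}
    for cond, vals in scores_by_condition.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size == 0:
            raise InvalidInputError(f"condition {cond!r} has no streams")
        means[cond] = float(vals.mean())
    ref = means[reference]
    if ref <= 0:
        raise InvalidInputError("reference condition mean must be positive")
    return RegularityScore(
        condition_means=means,
        reference=reference,
        normalized={c: m / ref for c, m in means.items()},
    )
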