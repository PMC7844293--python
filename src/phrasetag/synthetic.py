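"""Synthetic inputs with known ground truth for every pipeline stage.

Two generators stand in for data the pipeline would otherwise have to
download or record:

* a category-clustered embedding lexicon (one Gaussian cluster per
  grammatical category, with designated cross-category pairs — adjective
  vs noun, adjective vs verb — placed so their pairwise cosine similarities
  fall in a target window such as the retained band [0.75, 1]);
* multichannel epochs with sinusoidal components at chosen DFT bins whose
  per-trial phase is von Mises distributed around a fixed phase.  The von
  Mises concentration kappa is parameterised by a locking strength
  s in [0, 1] chosen so that the population mean resultant length equals s
  exactly: kappa = A^{-1}(s) with A(kappa) = I1(kappa) / I0(kappa).  This
  gives every injected bin an analytically known expected ITPC.

The synthetic lexicon uses isotropic Gaussian perturbations and makes no
attempt to mimic the anisotropy of real distributional embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .design import FS_HZ, analysed_duration_s
from .errors import InvalidInputError
from .itpc import PhaseSet
from .lexicon import Category, WordToken, cosine_similarity
from .preprocess import EEGEpoch

DEFAULT_CATEGORIES = tuple(Category)
#: category pairs whose cross similarities are steered into the target window
DEFAULT_DESIGNATED_PAIRS = (
    (Category.ADJ, Category.NOUN),
    (Category.ADJ, Category.VERB),
)


@dataclass(frozen=True)
class SyntheticLexiconSpec:
    n_per_category: int = 30
    dim: int = 300
    categories: tuple[Category, ...] = DEFAULT_CATEGORIES
    designated_pairs: tuple[tuple[Category, Category], ...] = DEFAULT_DESIGNATED_PAIRS
    center_norm: float = 3.0           # fastText-like vector scale
    center_cosine: float = 0.93        # cosine between designated cluster centres
    #: perturbation norm relative to center_norm, for categories involved in
    #: designated pairs (content clusters: ADJ, NOUN, VERB by default)
    within_category_spread: float = 0.35
    #: spread for the remaining categories; function words in real
    #: embeddings are far more word-specific than content clusters, and this
    #: word-level variation is what decorrelates the shuffled condition's
    #: phases across embedding components
    function_category_spread: float = 1.2
    target_cross_similarity: tuple[float, float] = (0.75, 1.0)
    min_fraction_in_target: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if self.within_category_spread < 0:
            raise InvalidInputError("spread must be nonnegative")
        lo, hi = self.target_cross_similarity
        if not -1.0 <= lo < hi <= 1.0:
            raise InvalidInputError("target similarity interval must be within [-1, 1]")


def _cluster_centers(spec: SyntheticLexiconSpec, rng: np.random.Generator) -> dict[Category, np.ndarray]:
    """Random unit directions per category; designated partners are rotated
    to sit at ``center_cosine`` from their anchor category."""
    centers: dict[Category, np.ndarray] = {}
    for cat in spec.categories:
        v = rng.standard_normal(spec.dim)
        centers[cat] = v / np.linalg.norm(v)
    for anchor, partner in spec.designated_pairs:
        a = centers[anchor]
        p = centers[partner]
        perp = p - (p @ a) * a
        perp /= np.linalg.norm(perp)
        c = spec.center_cosine
        centers[partner] = c * a + np.sqrt(1.0 - c * c) * perp
    return {cat: spec.center_norm * v for cat, v in centers.items()}


def generate_category_lexicon(spec: SyntheticLexiconSpec = SyntheticLexiconSpec()) -> list[WordToken]:
    """Category-clustered lexicon: centre + isotropic Gaussian perturbation.

    The perturbation scale starts at ``within_category_spread`` (relative to
    the centre norm) and is shrunk geometrically until at least
    ``min_fraction_in_target`` of each designated pair's cross similarities
    fall inside ``target_cross_similarity``; if that never happens the error
    reports the achieved range.
    """
    rng = np.random.default_rng(spec.seed)
    centers = _cluster_centers(spec, rng)
    # perturbation directions drawn once; only the scale is annealed, so the
    # lexicon is a deterministic function of (spec, seed)
    raw = {
        cat: rng.standard_normal((spec.n_per_category, spec.dim))
        for cat in spec.categories
    }
    lo, hi = spec.target_cross_similarity
    designated = {c for pair in spec.designated_pairs for c in pair}
    spread = spec.within_category_spread
    for _ in range(8):
        # only the designated (content) clusters are annealed; the
        # target-window constraint does not involve the other categories
        def sigma(cat):
            s = spread if cat in designated else spec.function_category_spread
            return s * spec.center_norm / np.sqrt(spec.dim)

        vectors = {cat: centers[cat] + sigma(cat) * raw[cat] for cat in spec.categories}
        fractions = []
        for ca, cb in spec.designated_pairs:
            sims = _cross_cosines(vectors[ca], vectors[cb])
            fractions.append(np.mean((sims >= lo) & (sims <= hi)))
        if all(f >= spec.min_fraction_in_target for f in fractions) or spread == 0:
            lexicon = []
            for cat in spec.categories:
                for i in range(spec.n_per_category):
                    lexicon.append(
                        WordToken(f"{cat.value.lower()}{i:02d}", cat, vectors[cat][i])
                    )
            return lexicon
        spread *= 0.8
    achieved = [
        (ca.value, cb.value, float(sims.min()), float(sims.max()))
        for (ca, cb) in spec.designated_pairs
        for sims in [_cross_cosines(vectors[ca], vectors[cb])]
    ]
    raise InvalidInputError(
        f"target cross-similarity {spec.target_cross_similarity} infeasible; achieved {achieved}"
    )


def _cross_cosines(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    An = A / np.linalg.norm(A, axis=1, keepdims=True)
    Bn = B / np.linalg.norm(B, axis=1, keepdims=True)
    return (An @ Bn.T).ravel()


def mean_resultant_length(kappa: float) -> float:
    """A(kappa) = I1(kappa)/I0(kappa): von Mises population ITPC."""
    if np.isinf(kappa):
        return 1.0
    if kappa == 0.0:
        return 0.0
    return float(special.i1e(kappa) / special.i0e(kappa))


def strength_to_kappa(strength: float) -> float:
    """Invert A(kappa) so that locking strength = population mean resultant.

    strength 0 -> kappa 0 (uniform phases); strength 1 -> kappa = inf
    (zero dispersion).
    """
    if not 0.0 <= strength <= 1.0:
        raise InvalidInputError("strength must be in [0, 1]")
    if strength == 0.0:
        return 0.0
    if strength == 1.0:
        return float("inf")
    return float(optimize.brentq(lambda k: mean_resultant_length(k) - strength, 1e-12, 1e6))


@dataclass(frozen=True)
class SyntheticEEGSpec:
    #: (bin index, locking strength in [0,1], fixed phase in radians)
    injected_bins: tuple[tuple[int, float, float], ...] = ((24, 1.0, 0.0),)
    jitter_ms: float = 0.0
    noise_amplitude: float = 0.0  # pink-noise amplitude per channel
    n_trials: int = 24
    n_channels: int = 32
    fs: float = FS_HZ
    duration_s: float = analysed_duration_s()
    amplitude: float = 1.0
    seed: int = 0

    def __post_init__(self):
        n = round(self.fs * self.duration_s)
        for b, s, _ in self.injected_bins:
            if not 0 < b <= n // 2:
                raise InvalidInputError(f"bin {b} outside (0, Nyquist bin {n // 2}]")
            if not 0.0 <= s <= 1.0:
                raise InvalidInputError("locking strength must be in [0, 1]")


def generate_locked_eeg(spec: SyntheticEEGSpec = SyntheticEEGSpec()) -> tuple[list[EEGEpoch], dict]:
    """Trials of phase-locked sinusoids plus optional jitter and pink noise.

    Per trial, each injected bin contributes a sinusoid at the bin frequency
    whose phase is the fixed phase plus von Mises dispersion (kappa from the
    strength) plus the phase shift induced by a uniform onset jitter.  The
    sinusoid is common to all channels (a single source); pink noise is
    independent per channel.  Returns the epochs (already at analysed
    length, marked trimmed) and a ground-truth dict per bin.
    """
    from .fictive import _pink  # local import to avoid a module cycle

    rng = np.random.default_rng(spec.seed)
    n = round(spec.fs * spec.duration_s)
    t = np.arange(n) / spec.fs
    truth = {
        int(b): {"strength": float(s), "phase": float(ph), "kappa": strength_to_kappa(s)}
        for b, s, ph in spec.injected_bins
    }
    epochs = []
    for trial in range(spec.n_trials):
        t0 = rng.uniform(0.0, spec.jitter_ms / 1000.0) if spec.jitter_ms > 0 else 0.0
        x = np.zeros(n)
        for b, s, ph in spec.injected_bins:
            kappa = truth[b]["kappa"]
            if np.isinf(kappa):
                theta = ph
            elif kappa == 0.0:
                theta = rng.uniform(0.0, 2.0 * np.pi)
            else:
                theta = ph + rng.vonmises(0.0, kappa)
            f = b / spec.duration_s
            x += spec.amplitude * np.cos(2.0 * np.pi * f * (t - t0) + theta)
        data = np.tile(x, (spec.n_channels, 1))
        if spec.noise_amplitude > 0:
            data = data + spec.noise_amplitude * _pink(rng, (spec.n_channels, n))
        epochs.append(
            EEGEpoch(
                data=data,
                fs=spec.fs,
                trimmed=True,
                meta={"participant": "synth", "condition": "SYNTH", "stream_id": f"trial{trial:03d}"},
            )
        )
    return epochs, truth


def random_phases(K: int, seed: int = 0) -> PhaseSet:
    """K independent phases uniform on [0, 2*pi)."""
    if K < 1:
        raise InvalidInputError("K must be >= 1")
    rng = np.random.default_rng(seed)
    return PhaseSet(rng.uniform(0.0, 2.0 * np.pi, size=K))
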