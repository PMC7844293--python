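"""Significance machinery: random-phase ITPC null, nonparametric condition
comparisons, and exact tests for the behavioural contingency tables.

The chance level of an electrode-averaged ITPC is obtained by Monte Carlo:
each replicate mimics the data pipeline by drawing K uniform phases per
"electrode", computing R, and averaging over the electrode count.  Observed
per-participant ITPCs are compared to the replicates with a one-sided
Mann-Whitney U test (unpaired by construction).  Condition effects use
Kruskal-Wallis and pairwise Wilcoxon signed-rank tests without multiplicity
correction; the behavioural two-alternative judgments use one-sided Fisher
exact tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats as sst

from .errors import InvalidInputError


@dataclass
class NullDistribution:
    """Monte-Carlo null of electrode-averaged ITPC values."""

    values: np.ndarray
    K: int
    n_electrodes: int
    seed: int | None = None
    _sorted: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self._sorted = np.sort(self.values)

    @property
    def sorted_values(self) -> np.ndarray:
        return self._sorted

    @property
    def n_rep(self) -> int:
        return self.values.size

    def confidence_interval(self, level: float = 0.95) -> tuple[float, float]:
        """Order-statistic interval at 1-based ranks n*(1-level) and n*level.

        For 5000 replicates at level 0.95 this is the 250th and 4750th
        sorted entries — the rank convention used to draw the chance-level
        band on the per-participant figures.
        """
        n = self.n_rep
        lo_rank = max(1, round(n * (1 - level)))
        hi_rank = min(n, round(n * level))
        return float(self._sorted[lo_rank - 1]), float(self._sorted[hi_rank - 1])

    def mean(self) -> float:
        return float(self.values.mean())


def rayleigh_null_mean(K: int) -> float:
    """Large-K expectation of R under uniform phases: (1/2) sqrt(pi / K)."""
    return 0.5 * float(np.sqrt(np.pi / K))


def simulate_null_itpc(
    K: int = 24,
    n_electrodes: int = 32,
    n_rep: int = 5000,
    seed: int = 0,
    chunk_size: int | None = None,
) -> NullDistribution:
    """Simulate the electrode-averaged ITPC null distribution.

    Each replicate draws K uniform phases for each of ``n_electrodes``
    electrodes, computes R per electrode and averages.  ``chunk_size``
    partitions the replicate loop (for memory); the random stream is
    consumed in the same order regardless, so results are identical.
    """
    if K < 2 or n_electrodes < 1 or n_rep < 100:
        raise InvalidInputError("require K >= 2, n_electrodes >= 1, n_rep >= 100")
    rng = np.random.default_rng(seed)
    chunk = n_rep if chunk_size is None else int(chunk_size)
    out = np.empty(n_rep)
    done = 0
    while done < n_rep:
        m = min(chunk, n_rep - done)
        theta = rng.uniform(0.0, 2.0 * np.pi, size=(m, n_electrodes, K))
        r = np.abs(np.exp(1j * theta).mean(axis=-1))  # (m, n_electrodes)
        out[done : done + m] = r.mean(axis=-1)
        done += m
    return NullDistribution(out, K=K, n_electrodes=n_electrodes, seed=seed)


def peak_significance(observed, null: NullDistribution) -> float:
    """One-sided Mann-Whitney U p-value that the observed ITPCs exceed the
    null replicates (asymptotic with tie correction)."""
    observed = np.atleast_1d(np.asarray(observed, dtype=float))
    if observed.size == 0 or null.n_rep == 0:
        raise InvalidInputError("empty observed values or null distribution")
    res = sst.mannwhitneyu(observed, null.values, alternative="greater", method="asymptotic")
    return float(res.pvalue)


def compare_conditions(groups) -> float:
    """Kruskal-Wallis p-value across condition groups of per-participant ITPCs.

    ``groups`` is a mapping condition -> values or a sequence of value arrays.
    """
    if hasattr(groups, "values") and not isinstance(groups, np.ndarray):
        arrays = [np.asarray(v, float) for v in groups.values()]
    else:
        arrays = [np.asarray(v, float) for v in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise InvalidInputError("need >= 2 groups with >= 2 values each")
    if np.ptp(np.concatenate(arrays)) == 0:
        raise InvalidInputError("all values identical; Kruskal-Wallis undefined")
    return float(sst.kruskal(*arrays).pvalue)


def pairwise_condition_tests(
    values_by_condition: dict[str, np.ndarray],
    comparisons: list[tuple[str, str, str]],
) -> dict[tuple[str, str], float]:
    """Paired Wilcoxon signed-rank tests between named conditions.

    ``comparisons`` lists (condition_a, condition_b, alternative) with
    alternative in {"greater", "less", "two-sided"}; no multiplicity
    correction is applied.  Zero differences are dropped; if every
    difference is zero the p-value is reported as NaN (undefined).
    """
    out: dict[tuple[str, str], float] = {}
    for ca, cb, alternative in comparisons:
        x = np.asarray(values_by_condition[ca], float)
        y = np.asarray(values_by_condition[cb], float)
        if x.shape != y.shape:
            raise InvalidInputError(f"paired vectors differ in length for {ca} vs {cb}")
        if np.all(x == y):
            out[(ca, cb)] = float("nan")
            continue
        res = sst.wilcoxon(x, y, alternative=alternative, zero_method="wilcox")
        out[(ca, cb)] = float(res.pvalue)
    return out


@dataclass
class BehavioralTable:
    """2x2 counts: rows = two conditions, columns = (judged "phrases",
    judged "random")."""

    counts: np.ndarray
    row_labels: tuple[str, str] = ("condition_1", "condition_2")

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (2, 2):
            raise InvalidInputError("behavioural table must be 2x2")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            raise InvalidInputError("counts must be nonnegative integers")

    @property
    def n_subjects(self) -> int:
        return int(self.counts.sum())


def fisher_exact_one_sided(table: BehavioralTable | np.ndarray) -> float:
    """Exact one-sided Fisher test that row 1 is enriched for column 1.

    The p-value is the hypergeometric tail probability, given the margins,
    that the top-left count is at least as large as observed.
    """
    counts = table.counts if isinstance(table, BehavioralTable) else np.asarray(table)
    table = BehavioralTable(counts) if not isinstance(table, BehavioralTable) else table
    c = table.counts
    if np.any(c.sum(axis=0) == 0) or np.any(c.sum(axis=1) == 0):
        raise InvalidInputError("table has a zero margin")
    a = int(c[0, 0])
    M = int(c.sum())              # population size
    n_draw = int(c[0].sum())      # row-1 group size
    n_success = int(c[:, 0].sum())  # total "phrases" judgments
    return float(sst.hypergeom.sf(a - 1, M, n_success, n_draw))


def round_p(p: float, ndigits: int = 3) -> float:
    """Round half-up to ``ndigits`` decimals (printed-value convention)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(p)).quantize(q, rounding=ROUND_HALF_UP))
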