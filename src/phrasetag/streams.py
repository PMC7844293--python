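"""Construction of the four condition-specific 52-word streams.

Conditions
----------
AN
    Strict adjective-noun alternation, chained greedily so that each
    consecutive cross-category pair has similarity close to that of the
    preceding pair (similarity-matched chaining over a retained pair set).
AV
    Identical algorithm over adjective-verb pairs: category regularity is
    preserved, but no grammatical phrase can be formed.
MP
    26 contiguous grammatical two-word phrases of mixed types, with no two
    adjacent phrases of the same type and no grammatical phrase straddling
    a phrase boundary.
RR
    Random words from the non-noun pool, with no adjacent category pair
    forming a grammatical phrase (and, by default, no repeated category in
    adjacent positions).
SHUF
    A uniformly shuffled stream; the simulator's fully random reference
    condition.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import InvalidInputError, StreamConstructionError
from .lexicon import Category, WordToken, cosine_similarity

STREAM_LENGTH = 52
DEFAULT_RETRY_BUDGET = 100


class Condition(str, enum.Enum):
    AN = "AN"
    AV = "AV"
    MP = "MP"
    RR = "RR"
    SHUF = "SHUF"


#: Ordered category bigrams that form a grammatical two-word phrase.
#: ADJ-NOUN is part of the grammar (a "loud fish" style noun phrase) even
#: though it is not one of the mixed-phrase construction types below.
DEFAULT_PHRASE_GRAMMAR: frozenset[tuple[Category, Category]] = frozenset(
    {
        (Category.VERB, Category.NOUN),
        (Category.VERB, Category.ADJ),
        (Category.ADV, Category.ADJ),
        (Category.DET, Category.NOUN),
        (Category.PREP, Category.NOUN),
        (Category.VERB, Category.ADV),
        (Category.ADJ, Category.NOUN),
    }
)

#: Phrase types actually sampled when building MP streams.
MP_PHRASE_TYPES: tuple[tuple[Category, Category], ...] = (
    (Category.VERB, Category.NOUN),
    (Category.VERB, Category.ADJ),
    (Category.ADV, Category.ADJ),
    (Category.DET, Category.NOUN),
    (Category.PREP, Category.NOUN),
    (Category.VERB, Category.ADV),
)

#: Categories admitted into RR streams (nouns excluded: they phrase too easily).
RR_CATEGORIES: frozenset[Category] = frozenset(
    {Category.ADJ, Category.VERB, Category.PREP, Category.DET}
)


@dataclass(frozen=True)
class PhraseGrammar:
    """The set of ordered category bigrams counted as grammatical phrases."""

    allowed_bigrams: frozenset[tuple[Category, Category]] = DEFAULT_PHRASE_GRAMMAR

    def __contains__(self, bigram: tuple[Category, Category]) -> bool:
        return bigram in self.allowed_bigrams


@dataclass
class Stream:
    """An ordered 52-word stimulus stream with its condition label."""

    tokens: list[WordToken]
    condition: Condition
    stream_id: str

    @property
    def forms(self) -> list[str]:
        return [t.form for t in self.tokens]

    @property
    def categories(self) -> list[Category]:
        return [t.category for t in self.tokens]

    def vectors(self) -> np.ndarray:
        """(n_words, dim) embedding matrix in stream order."""
        return np.stack([t.embedding for t in self.tokens])


def validate_stream(
    stream: Stream,
    grammar: PhraseGrammar = PhraseGrammar(),
    length: int = STREAM_LENGTH,
) -> list[str]:
    """Return a list of invariant violations (empty when the stream is valid).

    Checks the shared invariants (length, no repeated word form) plus the
    per-condition ones: strict ADJ/NOUN or ADJ/VERB alternation for AN/AV;
    the phrase-type and boundary constraints for MP; the no-noun and
    no-grammar-bigram constraints for RR.
    """
    problems: list[str] = []
    cats = stream.categories
    if len(stream.tokens) != length:
        problems.append(f"expected {length} tokens, got {len(stream.tokens)}")
    dup = [f for f, n in Counter(stream.forms).items() if n > 1]
    if dup:
        problems.append(f"repeated word forms: {sorted(dup)}")

    if stream.condition in (Condition.AN, Condition.AV):
        second = Category.NOUN if stream.condition is Condition.AN else Category.VERB
        expect = [Category.ADJ if i % 2 == 0 else second for i in range(len(cats))]
        if cats != expect:
            problems.append(f"{stream.condition.value} stream does not strictly alternate ADJ/{second.value}")
    elif stream.condition is Condition.MP:
        if len(cats) % 2:
            problems.append("MP stream has an odd number of tokens")
        else:
            phrases = [(cats[2 * i], cats[2 * i + 1]) for i in range(len(cats) // 2)]
            for i, ph in enumerate(phrases):
                if ph not in grammar:
                    problems.append(f"phrase {i} {ph} not an allowed bigram")
            for i in range(len(phrases) - 1):
                if phrases[i] == phrases[i + 1]:
                    problems.append(f"adjacent phrases {i},{i + 1} share type {phrases[i]}")
                boundary = (phrases[i][1], phrases[i + 1][0])
                if boundary in grammar:
                    problems.append(f"grammatical phrase {boundary} across boundary {i}|{i + 1}")
    elif stream.condition is Condition.RR:
        if Category.NOUN in cats:
            problems.append("RR stream contains NOUN tokens")
        for i in range(len(cats) - 1):
            if (cats[i], cats[i + 1]) in grammar:
                problems.append(f"grammatical bigram {(cats[i], cats[i + 1])} at position {i}")
    return problems


def _canonical_pairs(
    pairs: Iterable[tuple[WordToken, WordToken]]
) -> list[tuple[WordToken, WordToken]]:
    # deterministic ordering regardless of input set/iteration order
    return sorted(pairs, key=lambda p: (p[0].form, p[1].form))


def build_alternating_stream(
    pairs: Iterable[tuple[WordToken, WordToken]],
    length: int = STREAM_LENGTH,
    seed: int = 0,
    condition: Condition | None = None,
    stream_id: str = "",
    retry_budget: int = DEFAULT_RETRY_BUDGET,
) -> Stream:
    """Greedy similarity-matched chain over a retained cross-category pair set.

    Starting from a seeded initial pair (A1, N1), the next first-category
    word A2 != A1 is the one whose similarity to N1 is closest to
    sim(A1, N1); then N2 is the second-category word whose similarity to A2
    is closest to sim(N1, A2); and so on until ``length`` words are chosen,
    never repeating a word form.  Candidates are restricted to words that
    form a retained pair with the previous word.  Ties on similarity
    closeness break to the lexicographically smaller form.  A stuck chain
    restarts from the next seeded initial pair, up to ``retry_budget``
    attempts.
    """
    plist = _canonical_pairs(pairs)
    if not plist:
        raise InvalidInputError("retained pair set is empty; relax the similarity window")
    if length % 2:
        raise InvalidInputError("alternating streams need an even length")
    cat_a = plist[0][0].category
    cat_b = plist[0][1].category
    if condition is None:
        condition = Condition.AN if cat_b is Category.NOUN else Condition.AV

    # adjacency maps with precomputed similarities, deterministic candidate order
    sim: dict[tuple[str, str], float] = {}
    by_first: dict[WordToken, list[WordToken]] = {}
    by_second: dict[WordToken, list[WordToken]] = {}
    for a, b in plist:
        sim[(a.form, b.form)] = cosine_similarity(a.embedding, b.embedding)
        by_first.setdefault(a, []).append(b)
        by_second.setdefault(b, []).append(a)
    for lst in by_first.values():
        lst.sort(key=lambda t: t.form)
    for lst in by_second.values():
        lst.sort(key=lambda t: t.form)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(plist))
    diagnostics: Counter[str] = Counter()

    for attempt_idx in range(min(retry_budget, len(plist))):
        a1, b1 = plist[order[attempt_idx]]
        chain = [a1, b1]
        used = {a1.form, b1.form}
        target = sim[(a1.form, b1.form)]
        while len(chain) < length:
            prev = chain[-1]
            if prev.category is cat_b:
                cands = [w for w in by_second.get(prev, []) if w.form not in used]
                key = lambda w: sim[(w.form, prev.form)]  # noqa: E731
            else:
                cands = [w for w in by_first.get(prev, []) if w.form not in used]
                key = lambda w: sim[(prev.form, w.form)]  # noqa: E731
            if not cands:
                diagnostics["chain stuck (no unused linked word)"] += 1
                break
            # closest similarity to the previous link; ties -> smaller form
            best = min(cands, key=lambda w: (abs(key(w) - target), w.form))
            target = key(best)
            chain.append(best)
            used.add(best.form)
        else:
            return Stream(chain, condition, stream_id or f"{condition.value}-{seed}")
    raise StreamConstructionError(
        f"could not chain {length} words in {retry_budget} attempts", diagnostics
    )


def _group_by_category(lexicon: Iterable[WordToken]) -> dict[Category, list[WordToken]]:
    groups: dict[Category, list[WordToken]] = {}
    for t in lexicon:
        groups.setdefault(t.category, []).append(t)
    for lst in groups.values():
        lst.sort(key=lambda t: t.form)
    return groups


def build_mp_stream(
    lexicon: Iterable[WordToken],
    grammar: PhraseGrammar = PhraseGrammar(),
    seed: int = 0,
    phrase_types: Sequence[tuple[Category, Category]] = MP_PHRASE_TYPES,
    n_phrases: int = STREAM_LENGTH // 2,
    stream_id: str = "",
    retry_budget: int = DEFAULT_RETRY_BUDGET,
) -> Stream:
    """Mixed-phrase stream: seeded rejection sampling over phrase-type
    sequences and word fills.

    Constraints: every phrase is an allowed bigram; adjacent phrases differ
    in type; the category pair across each phrase boundary is *not* in the
    grammar (so no grammatical phrase forms across boundaries); no word form
    repeats.
    """
    groups = _group_by_category(lexicon)
    for ca, cb in phrase_types:
        if ca not in groups or cb not in groups:
            raise InvalidInputError(f"lexicon lacks tokens for phrase type {ca.value}-{cb.value}")
    rng = np.random.default_rng(seed)
    diagnostics: Counter[str] = Counter()
    types = list(phrase_types)

    for _ in range(retry_budget):
        # phrase-type sequence satisfying the type-level constraints
        seq: list[tuple[Category, Category]] = []
        ok = True
        for _i in range(n_phrases):
            legal = [
                t
                for t in types
                if not seq
                or (t != seq[-1] and (seq[-1][1], t[0]) not in grammar)
            ]
            if not legal:
                diagnostics["no legal phrase type continuation"] += 1
                ok = False
                break
            seq.append(legal[rng.integers(len(legal))])
        if not ok:
            continue
        # word fill without repetition
        used: set[str] = set()
        tokens: list[WordToken] = []
        for ca, cb in seq:
            picked = []
            for cat in (ca, cb):
                avail = [w for w in groups[cat] if w.form not in used]
                if not avail:
                    diagnostics[f"category {cat.value} exhausted"] += 1
                    ok = False
                    break
                w = avail[rng.integers(len(avail))]
                used.add(w.form)
                picked.append(w)
            if not ok:
                break
            tokens.extend(picked)
        if ok:
            stream = Stream(tokens, Condition.MP, stream_id or f"MP-{seed}")
            assert not validate_stream(stream, grammar, length=2 * n_phrases)
            return stream
    raise StreamConstructionError(
        f"MP construction failed after {retry_budget} attempts", diagnostics
    )


def build_rr_stream(
    lexicon: Iterable[WordToken],
    grammar: PhraseGrammar = PhraseGrammar(),
    seed: int = 0,
    length: int = STREAM_LENGTH,
    forbid_category_repeat: bool = True,
    stream_id: str = "",
    retry_budget: int = DEFAULT_RETRY_BUDGET,
) -> Stream:
    """Random-word stream from the non-noun pool.

    Words are sampled without replacement from adjectives, verbs,
    prepositions and determiners such that no adjacent category bigram is a
    grammatical phrase; by default adjacent words may not repeat a category
    either (the pseudo-random construction the simulator's shuffled
    reference is contrasted against).
    """
    pool = sorted(
        (t for t in lexicon if t.category in RR_CATEGORIES), key=lambda t: t.form
    )
    if len(pool) < length:
        raise InvalidInputError(
            f"need at least {length} distinct non-noun tokens, have {len(pool)}"
        )
    rng = np.random.default_rng(seed)
    diagnostics: Counter[str] = Counter()
    for _ in range(retry_budget):
        used: set[str] = set()
        tokens: list[WordToken] = []
        ok = True
        for _i in range(length):
            prev_cat = tokens[-1].category if tokens else None
            cands = [
                w
                for w in pool
                if w.form not in used
                and (
                    prev_cat is None
                    or (
                        (prev_cat, w.category) not in grammar
                        and (not forbid_category_repeat or w.category is not prev_cat)
                    )
                )
            ]
            if not cands:
                diagnostics["no legal next word"] += 1
                ok = False
                break
            w = cands[rng.integers(len(cands))]
            used.add(w.form)
            tokens.append(w)
        if ok:
            return Stream(tokens, Condition.RR, stream_id or f"RR-{seed}")
    raise StreamConstructionError(
        f"RR construction failed after {retry_budget} attempts", diagnostics
    )
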