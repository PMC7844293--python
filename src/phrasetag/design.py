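"""Design arithmetic of the frequency-tagging paradigm.

All timing and frequency constants of the experiment derive from two
numbers: the 320 ms word (syllable) duration and the 52-word stream of
which the first 4 words are discarded before analysis.  Everything here is
computed from those primitives so the arithmetic is checkable rather than
asserted.
"""

from __future__ import annotations

WORD_MS: int = 320          # duration of one monosyllabic word
WORDS_PER_STREAM: int = 52  # words played per stream
WORDS_DROPPED: int = 4      # onset words removed before analysis
FS_HZ: float = 1000.0       # sampling rate of both real and fictive EEG

#: DFT bin index of the two-word (phrase) rate in the analysed epoch.
PHRASE_BIN: int = 24
#: DFT bin index of the word (syllable) rate in the analysed epoch.
SYLLABLE_BIN: int = 48


def stream_duration_s(n_words: int = WORDS_PER_STREAM, word_ms: int = WORD_MS) -> float:
    """Total played duration of one stream, in seconds."""
    return n_words * word_ms / 1000.0


def analysed_duration_s(
    n_words: int = WORDS_PER_STREAM,
    word_ms: int = WORD_MS,
    words_dropped: int = WORDS_DROPPED,
) -> float:
    """Duration of the analysed (onset-trimmed) part of an epoch, in seconds."""
    return (n_words - words_dropped) * word_ms / 1000.0


def frequency_resolution_hz(**kwargs) -> float:
    """DFT bin spacing for the analysed epoch (reciprocal of its duration)."""
    return 1.0 / analysed_duration_s(**kwargs)


def bin_frequency_hz(bin_index: int, **kwargs) -> float:
    """Centre frequency of a DFT bin of the analysed epoch."""
    return bin_index * frequency_resolution_hz(**kwargs)


def syllable_rate_hz(word_ms: int = WORD_MS) -> float:
    """Word presentation rate in Hz (one word per ``word_ms``)."""
    return 1000.0 / word_ms


def phrase_rate_hz(word_ms: int = WORD_MS) -> float:
    """Two-word sequence presentation rate in Hz."""
    return syllable_rate_hz(word_ms) / 2.0


def assert_tag_bins_on_grid() -> None:
    """Check that both tag rates fall exactly on DFT bin centres.

    The analysed-epoch duration is an integer number of word periods, so
    the syllable and phrase rates coincide with bins ``SYLLABLE_BIN`` and
    ``PHRASE_BIN`` exactly; this guards against configuration drift.
    """
    df = frequency_resolution_hz()
    if PHRASE_BIN * df != phrase_rate_hz() or SYLLABLE_BIN * df != syllable_rate_hz():
        raise AssertionError(
            "tag frequencies do not sit on exact DFT bins: "
            f"phrase {PHRASE_BIN * df} vs {phrase_rate_hz()}, "
            f"syllable {SYLLABLE_BIN * df} vs {syllable_rate_hz()}"
        )
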