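"""Readers and writers for the pipeline's file formats.

Formats: fastText-style ``.vec`` text embeddings, a TSV word-category
table, stream TSVs, ITPC TSVs, and an npz epoch container with a JSON
sidecar carrying sampling rate and grouping metadata.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import InvalidInputError, ParseError
from .itpc import ITPCSpectrum
from .lexicon import Category, WordToken
from .preprocess import EEGEpoch
from .streams import Condition, Stream


def read_vec_embeddings(path: str | Path) -> dict[str, np.ndarray]:
    """Read a ``.vec`` file: header ``<count> <dim>``, then word + floats.

    Validates the header against the body (row count, dimension per row,
    duplicate words) and reports parse errors with line numbers.
    """
    path = Path(path)
    vectors: dict[str, np.ndarray] = {}
    with path.open() as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ParseError("header must be '<count> <dim>'", line=1)
        try:
            count, dim = int(header[0]), int(header[1])
        except ValueError:
            raise ParseError(f"non-integer header fields {header}", line=1) from None
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            word = parts[0]
            if len(parts) - 1 != dim:
                raise ParseError(
                    f"word {word!r} has {len(parts) - 1} components, header says {dim}",
                    line=lineno,
                )
            if word in vectors:
                raise ParseError(f"duplicate word {word!r}", line=lineno)
            try:
                vectors[word] = np.array(parts[1:], dtype=float)
            except ValueError:
                raise ParseError(f"malformed float in row for {word!r}", line=lineno) from None
    if len(vectors) != count:
        raise ParseError(f"header promises {count} rows, file has {len(vectors)}")
    return vectors


def write_vec_embeddings(path: str | Path, vectors: Mapping[str, np.ndarray],
                         precision: int = 6) -> None:
    path = Path(path)
    dims = {len(v) for v in vectors.values()}
    if len(dims) != 1:
        raise InvalidInputError(f"vectors mix dimensions: {sorted(dims)}")
    dim = dims.pop()
    with path.open("w") as fh:
        fh.write(f"{len(vectors)} {dim}\n")
        for word, vec in vectors.items():
            fh.write(word + " " + " ".join(f"{x:.{precision}g}" for x in vec) + "\n")


def read_category_table(path: str | Path) -> dict[str, Category]:
    """TSV with columns ``form`` and ``category``."""
    df = pd.read_csv(path, sep="\t")
    if not {"form", "category"} <= set(df.columns):
        raise ParseError(f"{path}: need columns form, category; got {list(df.columns)}")
    try:
        return {str(r.form): Category(str(r.category)) for r in df.itertuples()}
    except ValueError as e:
        raise ParseError(f"{path}: {e}") from None


def write_category_table(path: str | Path, lexicon: Iterable[WordToken]) -> None:
    pd.DataFrame(
        [(t.form, t.category.value) for t in lexicon], columns=["form", "category"]
    ).to_csv(path, sep="\t", index=False)


def build_lexicon(vectors: Mapping[str, np.ndarray],
                  categories: Mapping[str, Category]) -> list[WordToken]:
    """Join embeddings and the category table into WordTokens."""
    missing = sorted(set(categories) - set(vectors))
    if missing:
        raise InvalidInputError(f"no embedding for categorised words: {missing[:10]}")
    return [WordToken(w, categories[w], vectors[w]) for w in sorted(categories)]


def write_streams_tsv(path: str | Path, streams: Iterable[Stream]) -> None:
    rows = [
        (s.stream_id, s.condition.value, i, t.form, t.category.value)
        for s in streams
        for i, t in enumerate(s.tokens)
    ]
    pd.DataFrame(
        rows, columns=["stream_id", "condition", "position", "form", "category"]
    ).to_csv(path, sep="\t", index=False)


def read_streams_tsv(path: str | Path, lexicon: Iterable[WordToken]) -> list[Stream]:
    """Rebuild Stream objects from a stream TSV, attaching lexicon tokens."""
    by_form = {t.form: t for t in lexicon}
    df = pd.read_csv(path, sep="\t")
    streams = []
    for (sid, cond), grp in df.groupby(["stream_id", "condition"], sort=False):
        grp = grp.sort_values("position")
        try:
            tokens = [by_form[f] for f in grp["form"]]
        except KeyError as e:
            raise ParseError(f"stream {sid}: word {e} not in lexicon") from None
        streams.append(Stream(tokens, Condition(cond), str(sid)))
    return streams


def save_epoch(path: str | Path, epoch: EEGEpoch) -> None:
    """npz array container plus a JSON sidecar (same stem, ``.json``)."""
    path = Path(path)
    np.savez_compressed(path, data=epoch.data)
    sidecar = {
        "fs_hz": epoch.fs,
        "trimmed": epoch.trimmed,
        "channel_labels": epoch.channel_labels,
        **epoch.meta,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_epoch(path: str | Path) -> EEGEpoch:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    with np.load(path) as z:
        data = z["data"]
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return EEGEpoch(
        data=data,
        fs=float(sidecar.pop("fs_hz")),
        trimmed=bool(sidecar.pop("trimmed")),
        channel_labels=list(sidecar.pop("channel_labels")),
        meta=sidecar,
    )


def write_itpc_tsv(path: str | Path, spectrum: ITPCSpectrum) -> None:
    spectrum.table.to_csv(path, sep="\t", index=False)
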