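"""On-disk formats: attribute-value tables, word2vec files, coverage reports.

The canonical metadata table is a 4-column UTF-8 TSV with header
``sample_id  study_id  attribute  value``.  Values containing tabs or
newlines are quoted per standard TSV quoting; the reader and writer use
the same csv dialect so round-trips are exact.
"""

from __future__ import annotations

import csv
import io as _io
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .embedding import EmbeddingModel

__all__ = [
    "AttributeValueRecord",
    "read_records",
    "write_records",
    "records_to_frame",
    "read_embedding",
    "write_embedding",
    "coverage_report",
]

REQUIRED_COLUMNS = ("sample_id", "study_id", "attribute", "value")


@dataclass(frozen=True)
class AttributeValueRecord:
    """One (sample, study, attribute, value) metadata assertion.

    ``value`` may be empty — missing metadata is the whole point — but
    ``sample_id`` and ``attribute`` must be non-empty.
    """

    sample_id: str
    study_id: str
    attribute: str
    value: str

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if not self.attribute:
            raise ValueError("attribute must be non-empty")


class MissingColumnError(ValueError):
    """A required column is absent from an input table header."""


_DIALECT = dict(delimiter="\t", quotechar='"', quoting=csv.QUOTE_MINIMAL,
                lineterminator="\n")


def read_records(path, dialect: str = "tsv") -> list[AttributeValueRecord]:
    """Read attribute-value records from a TSV (or CSV) table.

    Rows that cannot be decoded as UTF-8 are skipped with a warning
    carrying the skipped-row count.  Duplicate (sample_id, attribute)
    rows keep the first occurrence, with a warning.
    """
    delim = "\t" if dialect == "tsv" else ","
    with open(path, "rb") as fh:
        raw = fh.read()
    lines = raw.split(b"\n")
    decoded: list[str] = []
    n_bad = 0
    for line in lines:
        try:
            decoded.append(line.decode("utf-8"))
        except UnicodeDecodeError:
            n_bad += 1
    if n_bad:
        warnings.warn(f"skipped {n_bad} row(s) with character encoding errors")
    text = "\n".join(decoded)
    if not text.strip():
        return []
    reader = csv.reader(_io.StringIO(text), delimiter=delim,
                        quotechar='"', lineterminator="\n")
    header = next(reader)
    for col in REQUIRED_COLUMNS:
        if col not in header:
            raise MissingColumnError(f"input table is missing required column {col!r}")
    pos = [header.index(c) for c in REQUIRED_COLUMNS]
    records: list[AttributeValueRecord] = []
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    for row in reader:
        if not row or all(not f for f in row):
            continue
        sample_id, study_id, attribute, value = (row[p] for p in pos)
        key = (sample_id, attribute)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        records.append(AttributeValueRecord(sample_id, study_id, attribute, value))
    if n_dup:
        warnings.warn(f"dropped {n_dup} duplicate (sample_id, attribute) row(s); kept first")
    return records


def write_records(path, records) -> None:
    """Write records as canonical 4-column TSV (UTF-8)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, **_DIALECT)
        writer.writerow(REQUIRED_COLUMNS)
        for rec in records:
            writer.writerow([rec.sample_id, rec.study_id, rec.attribute, rec.value])


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.sample_id, r.study_id, r.attribute, r.value) for r in records],
        columns=list(REQUIRED_COLUMNS),
    )


# ---------------------------------------------------------------------------
# word2vec formats

def read_embedding(path, format: str = "text", lowercase: bool = True) -> EmbeddingModel:
    """Read a word2vec text or binary file into an :class:`EmbeddingModel`.

    Both formats start with an ascii ``<vocab_size> <dim>`` header line.
    A row whose component count disagrees with the header is a fatal
    parse error reporting the offending line.
    """
    if format == "text":
        return _read_text_embedding(path, lowercase)
    if format == "binary":
        return _read_binary_embedding(path, lowercase)
    raise ValueError(f"unknown embedding format {format!r}")


def _read_text_embedding(path, lowercase: bool) -> EmbeddingModel:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: malformed word2vec header {header!r}")
        n_words, dim = int(header[0]), int(header[1])
        vocab: dict[str, int] = {}
        vectors = np.empty((n_words, dim), dtype=np.float64)
        for i in range(n_words):
            parts = fh.readline().rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise ValueError(
                    f"{path}: line {i + 2}: expected {dim} components, "
                    f"got {len(parts) - 1}"
                )
            vocab[parts[0]] = i
            vectors[i] = [float(x) for x in parts[1:]]
    return EmbeddingModel(vocab, vectors, lowercase=lowercase)


def _read_binary_embedding(path, lowercase: bool) -> EmbeddingModel:
    with open(path, "rb") as fh:
        header = fh.readline().split()
        n_words, dim = int(header[0]), int(header[1])
        vocab: dict[str, int] = {}
        vectors = np.empty((n_words, dim), dtype=np.float64)
        row_bytes = 4 * dim
        for i in range(n_words):
            word = bytearray()
            while True:
                ch = fh.read(1)
                if ch == b" ":
                    break
                if ch == b"":
                    raise ValueError(f"{path}: truncated at word {i + 1}")
                if ch != b"\n":  # tolerate newline padding between entries
                    word.extend(ch)
            buf = fh.read(row_bytes)
            if len(buf) != row_bytes:
                raise ValueError(
                    f"{path}: word {i + 1}: expected {dim} float32 components, "
                    f"got {len(buf) // 4}"
                )
            vocab[word.decode("utf-8")] = i
            vectors[i] = np.frombuffer(buf, dtype="<f4")
    return EmbeddingModel(vocab, vectors, lowercase=lowercase)


def write_embedding(path, model: EmbeddingModel, format: str = "text") -> None:
    """Write an :class:`EmbeddingModel` in word2vec text or binary format."""
    n, dim = model.vectors.shape
    if format == "text":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(f"{n} {dim}\n")
            for i in range(n):
                comps = " ".join(format_float(x) for x in model.vectors[i])
                fh.write(f"{model.token(i)} {comps}\n")
    elif format == "binary":
        with open(path, "wb") as fh:
            fh.write(f"{n} {dim}\n".encode("ascii"))
            for i in range(n):
                fh.write(model.token(i).encode("utf-8") + b" ")
                fh.write(model.vectors[i].astype("<f4").tobytes())
                fh.write(b"\n")
    else:
        raise ValueError(f"unknown embedding format {format!r}")


def format_float(x: float) -> str:
    return np.format_float_positional(x, precision=8, trim="-")


# ---------------------------------------------------------------------------
# coverage landscape

def coverage_report(records, total_samples: int, defined_attributes=frozenset()) -> pd.DataFrame:
    """Per-attribute annotation coverage and mean value length.

    Returns a frame indexed by attribute with columns
    ``percent_of_samples_annotated`` (100 x distinct annotated samples /
    total_samples), ``mean_value_character_length`` and
    ``is_user_defined`` (attribute not in *defined_attributes*), sorted
    by descending coverage.  Attributes never observed are absent.
    """
    if total_samples <= 0:
        raise ValueError("total_samples must be positive")
    frame = records_to_frame(records)
    n_distinct = frame["sample_id"].nunique()
    if total_samples < n_distinct:
        raise ValueError(
            f"total_samples={total_samples} is less than the {n_distinct} "
            "distinct samples present in the records"
        )
    if frame.empty:
        return pd.DataFrame(
            columns=["percent_of_samples_annotated",
                     "mean_value_character_length", "is_user_defined"]
        )
    grouped = frame.groupby("attribute")
    pct = 100.0 * grouped["sample_id"].nunique() / total_samples
    mean_len = grouped["value"].apply(lambda s: s.str.len().mean())
    report = pd.DataFrame(
        {
            "percent_of_samples_annotated": pct,
            "mean_value_character_length": mean_len,
            "is_user_defined": [a not in defined_attributes for a in pct.index],
        }
    )
    return report.sort_values("percent_of_samples_annotated", ascending=False)
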