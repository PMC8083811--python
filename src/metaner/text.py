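"""Shared tokenizer contract.

Every stage that touches free text (attribute values, attribute names,
sample titles) goes through the same tokenizer so that token counts,
embedding lookups and n-gram spans agree across modules: lowercase
(configurable at the embedding level), split on whitespace, strip
punctuation from token edges while keeping internal punctuation
(``rna-seq`` stays one token).
"""

from __future__ import annotations

import re
from importlib import resources

__all__ = [
    "tokenize",
    "split_sentences",
    "normalize_whitespace",
    "normalize_attribute_name",
    "load_stopwords",
    "default_stopwords",
]

# Characters stripped from token edges; internal occurrences are kept.
_EDGE_PUNCT = "!\"#$%&'()*+,./:;<=>?@[\\]^`{|}~"

# Sentence delimiters used for titles: semicolon, comma, full stop.
_SENTENCE_RE = re.compile(r"[;,.]")

_WS_RE = re.compile(r"\s+")


def normalize_whitespace(text: str) -> str:
    """Collapse whitespace runs to single spaces and trim the ends."""
    return _WS_RE.sub(" ", text).strip()


def tokenize(text: str, lowercase: bool = True) -> list[str]:
    """Split *text* on whitespace into punctuation-trimmed tokens.

    Empty tokens (e.g. a lone comma) are dropped.  This is the token
    count used by the value-length filter, so it is independent of any
    embedding vocabulary.
    """
    if lowercase:
        text = text.lower()
    tokens = []
    for raw in text.split():
        tok = raw.strip(_EDGE_PUNCT)
        if tok:
            tokens.append(tok)
    return tokens


def split_sentences(text: str) -> list[str]:
    """Split on the common sentence delimiters ``;``, ``,`` and ``.``.

    Empty fragments (consecutive delimiters) are removed.
    """
    return [frag for frag in (_SENTENCE_RE.split(text)) if frag.strip()]


def normalize_attribute_name(name: str) -> str:
    """Map punctuation in an attribute name to whitespace.

    Submitters write the same concept as ``cell type``, ``cell_type`` or
    ``Cell-Type``; mapping punctuation to spaces makes such variants
    tokenize identically.
    """
    out = []
    for ch in name:
        out.append(" " if (not ch.isalnum() and not ch.isspace()) else ch)
    return normalize_whitespace("".join(out)).lower()


def load_stopwords(path) -> frozenset[str]:
    """Read a one-token-per-line stop-word file (``#`` comments allowed)."""
    words = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                words.add(line.lower())
    return frozenset(words)


_DEFAULT_STOPWORDS: frozenset[str] | None = None


def default_stopwords() -> frozenset[str]:
    """The standard English stop-word list shipped with the package."""
    global _DEFAULT_STOPWORDS
    if _DEFAULT_STOPWORDS is None:
        ref = resources.files("metaner").joinpath("data/stopwords.txt")
        words = set()
        for line in ref.read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if line and not line.startswith("#"):
                words.add(line.lower())
        _DEFAULT_STOPWORDS = frozenset(words)
    return _DEFAULT_STOPWORDS
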