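"""Word-embedding substrate: vector lookup, phrase vectors, cosine.

A phrase vector is the unweighted arithmetic mean of the vectors of the
phrase's in-vocabulary tokens.  Out-of-vocabulary tokens are skipped,
not zero-imputed; a phrase whose every token is out of vocabulary has no
phrase vector.  All lookups lowercase the query by default, since the
typical pre-trained biomedical models are lowercased and metadata
capitalization is noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EmbeddingModel", "PhraseVector", "cosine"]


@dataclass
class PhraseVector:
    """Mean vector of a phrase's in-vocabulary tokens."""

    components: np.ndarray
    n_in_vocab: int

    def __post_init__(self) -> None:
        if self.n_in_vocab < 1:
            raise ValueError("a phrase vector needs at least one in-vocabulary token")


@dataclass
class EmbeddingModel:
    """Token -> dense vector map with a fixed dimension.

    Parameters
    ----------
    vocabulary
        Token -> row index into ``vectors``.
    vectors
        ``(|vocab|, dim)`` float matrix.
    lowercase
        Whether queries (and stored tokens) are lowercased before lookup.
    """

    vocabulary: dict[str, int]
    vectors: np.ndarray
    lowercase: bool = True
    _index_to_token: list[str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be a 2-D matrix")
        if len(self.vocabulary) != self.vectors.shape[0]:
            raise ValueError(
                f"vocabulary size {len(self.vocabulary)} does not match "
                f"vector count {self.vectors.shape[0]}"
            )
        norms = np.linalg.norm(self.vectors, axis=1)
        if np.any(norms == 0):
            bad = int(np.nonzero(norms == 0)[0][0])
            raise ValueError(f"all-zero vector at row {bad} is not admissible")
        if self.lowercase:
            lowered: dict[str, int] = {}
            for tok, idx in self.vocabulary.items():
                lowered.setdefault(tok.lower(), idx)  # first occurrence wins
            self.vocabulary = lowered
            if len(self.vocabulary) != self.vectors.shape[0]:
                keep = sorted(self.vocabulary.values())
                remap = {old: new for new, old in enumerate(keep)}
                self.vectors = self.vectors[keep]
                self.vocabulary = {t: remap[i] for t, i in self.vocabulary.items()}
        self._index_to_token = [""] * len(self.vocabulary)
        for tok, idx in self.vocabulary.items():
            self._index_to_token[idx] = tok

    @property
    def dim(self) -> int:
        return int(self.vectors.shape[1])

    def __len__(self) -> int:
        return len(self.vocabulary)

    def __contains__(self, token: str) -> bool:
        return self._normalize(token) in self.vocabulary

    def _normalize(self, token: str) -> str:
        return token.lower() if self.lowercase else token

    def index(self, token: str) -> int | None:
        """Row index of *token*, or None when out of vocabulary."""
        return self.vocabulary.get(self._normalize(token))

    def token(self, index: int) -> str:
        return self._index_to_token[index]

    def lookup(self, token: str) -> np.ndarray | None:
        """Stored vector for *token* after normalization; None when OOV."""
        idx = self.index(token)
        return None if idx is None else self.vectors[idx]

    def phrase_vector(self, tokens) -> PhraseVector | None:
        """Mean vector over the in-vocabulary tokens of *tokens*.

        Returns None when no token is in the vocabulary.  The mean is
        unweighted, so it is invariant to token order.
        """
        rows = [i for t in tokens if (i := self.index(t)) is not None]
        if not rows:
            return None
        return PhraseVector(self.vectors[rows].mean(axis=0), len(rows))


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity of two equal-dimension nonzero vectors."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine is undefined for zero-norm vectors")
    return float(np.dot(u, v) / (nu * nv))
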