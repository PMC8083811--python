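"""N-gram named-entity recognition over free-text sample titles.

The trained short-phrase classifier is applied to every 2- to 7-token
span of a preprocessed title.  A cascade of filters removes
uninformative candidates: spans with fewer than two in-vocabulary
tokens, spans whose top-category score sits within 0.01 of the
classifier's empty-string baseline, and spans whose top two category
scores differ by 0.1 or less.  Surviving spans are assigned to their
argmax category; overlapping same-category spans keep only the highest
scorer, and each category contributes at most one extraction per title.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classifier import BiLSTMClassifier
from .corpus import PAD_ID
from .embedding import EmbeddingModel
from .text import default_stopwords, normalize_whitespace, split_sentences, tokenize

__all__ = [
    "PreprocessedTitle",
    "NGramCandidate",
    "Extraction",
    "TitlePrediction",
    "preprocess_title",
    "title_length_gate",
    "enumerate_ngrams",
    "score_candidates",
    "score_and_filter",
    "filter_candidates",
    "resolve_overlaps",
    "TitleExtractor",
]


@dataclass
class PreprocessedTitle:
    """A title split into stop-word-free token sentences."""

    sentences: list[list[str]]
    original_text: str


@dataclass
class NGramCandidate:
    """A scored contiguous token span from one sentence of a title."""

    sentence_index: int
    start: int  # 0-based, half-open [start, end)
    end: int
    text: str
    n_in_vocab: int
    scores: np.ndarray | None = None
    top_category: int | None = None
    top_score: float = float("nan")
    margin: float = float("nan")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "NGramCandidate") -> bool:
        return (self.sentence_index == other.sentence_index
                and self.start < other.end and other.start < self.end)


@dataclass
class Extraction:
    text: str
    score: float
    sentence_index: int
    start: int
    end: int


@dataclass
class TitlePrediction:
    """At most one extraction per category for one title."""

    sample_id: str
    extractions: dict[str, Extraction] = field(default_factory=dict)
    skipped_reason: str | None = None
    survivors: list[NGramCandidate] = field(default_factory=list)


def title_length_gate(title: str, min_words: int = 5) -> bool:
    """True when the raw whitespace word count is strictly greater than
    *min_words* (titles of five or fewer words are skipped)."""
    return len(title.split()) > min_words


def preprocess_title(title: str, stop_words=None, lowercase: bool = True) -> PreprocessedTitle:
    """Sentence-split on ``;,.``, tokenize, drop empty tokens and stop words."""
    if stop_words is None:
        stop_words = default_stopwords()
    sentences = []
    for frag in split_sentences(title):
        toks = [t for t in tokenize(normalize_whitespace(frag), lowercase=lowercase)
                if t not in stop_words]
        if toks:
            sentences.append(toks)
    return PreprocessedTitle(sentences, title)


def enumerate_ngrams(tokens, n_min: int = 2, n_max: int = 7,
                     sentence_index: int = 0) -> list[NGramCandidate]:
    """All contiguous spans of *n_min* to *n_max* tokens, each once."""
    out = []
    L = len(tokens)
    for n in range(n_min, n_max + 1):
        for start in range(0, L - n + 1):
            out.append(NGramCandidate(
                sentence_index=sentence_index, start=start, end=start + n,
                text=" ".join(tokens[start:start + n]), n_in_vocab=0))
    return out


def _encode_span(tokens, model: EmbeddingModel, max_len: int) -> tuple[np.ndarray, int]:
    ids = [i + 1 for t in tokens if (i := model.index(t)) is not None]
    row = np.full(max_len, PAD_ID, dtype=np.int64)
    row[: len(ids)] = ids[:max_len]
    return row, len(ids)


def score_candidates(candidates, sentences, clf: BiLSTMClassifier,
                     model: EmbeddingModel) -> None:
    """Fill each candidate's score vector, argmax category and margin."""
    if not candidates:
        return
    rows = np.empty((len(candidates), clf.max_len), dtype=np.int64)
    for k, cand in enumerate(candidates):
        toks = sentences[cand.sentence_index][cand.start:cand.end]
        rows[k], cand.n_in_vocab = _encode_span(toks, model, clf.max_len)
    scores = clf.predict_proba(rows)
    for cand, s in zip(candidates, scores):
        cand.scores = s
        top = int(np.argmax(s))  # ties -> lowest category index
        cand.top_category = top
        cand.top_score = float(s[top])
        runner = float(np.partition(s, -2)[-2]) if len(s) > 1 else 0.0
        cand.margin = cand.top_score - runner


def score_and_filter(candidates, clf: BiLSTMClassifier, model: EmbeddingModel,
                     sentences, baseline: np.ndarray | None = None,
                     eps_baseline: float = 0.01, min_in_vocab: int = 2,
                     min_margin: float = 0.1,
                     baseline_mode: str = "argmax") -> list[NGramCandidate]:
    """Score candidates and apply the three-filter cascade.

    A candidate survives when (a) it has at least *min_in_vocab* tokens
    in the embedding vocabulary, (b) its score is not within
    *eps_baseline* of the empty-string baseline — by default compared at
    the assigned (argmax) category, or across all components with
    ``baseline_mode="all"`` — and (c) its top-vs-runner-up margin is
    strictly greater than *min_margin*.
    """
    if baseline is None:
        baseline = clf.baseline_scores_
    score_candidates(candidates, sentences, clf, model)
    return filter_candidates(candidates, baseline, eps_baseline=eps_baseline,
                             min_in_vocab=min_in_vocab, min_margin=min_margin,
                             baseline_mode=baseline_mode)


def filter_candidates(candidates, baseline, eps_baseline: float = 0.01,
                      min_in_vocab: int = 2, min_margin: float = 0.1,
                      baseline_mode: str = "argmax") -> list[NGramCandidate]:
    """Apply the filter cascade to already-scored candidates.

    Filter order is frozen (in-vocab, baseline, margin) for reproducible
    logs; the filters are independent predicates, so the order does not
    change the surviving set.
    """
    survivors = []
    for cand in candidates:
        if cand.n_in_vocab < min_in_vocab:
            continue
        if baseline_mode == "all":
            near = bool(np.all(np.abs(cand.scores - baseline) <= eps_baseline))
        else:
            near = abs(cand.top_score - baseline[cand.top_category]) <= eps_baseline
        if near:
            continue
        if cand.margin <= min_margin:
            continue
        survivors.append(cand)
    return survivors


def resolve_overlaps(survivors, categories, sample_id: str = "") -> TitlePrediction:
    """Keep the best same-category span among overlaps, then the single
    best span per category.

    Overlap resolution is per category: spans assigned to different
    categories may overlap freely.  Among same-category spans that share
    a token offset in the same sentence, only the highest scorer is
    retained; if several disjoint same-category spans remain, the single
    highest-scoring one populates the prediction.
    """
    pred = TitlePrediction(sample_id=sample_id)
    by_cat: dict[int, list[NGramCandidate]] = {}
    for cand in survivors:
        by_cat.setdefault(cand.top_category, []).append(cand)
    for cat_idx, cands in by_cat.items():
        cands = sorted(cands, key=lambda c: (-c.top_score, c.sentence_index,
                                             c.start, c.end))
        retained: list[NGramCandidate] = []
        for cand in cands:
            if not any(cand.overlaps(r) for r in retained):
                retained.append(cand)
        pred.survivors.extend(retained)
        best = retained[0]  # highest score first by sort order
        pred.extractions[categories[cat_idx]] = Extraction(
            best.text, best.top_score, best.sentence_index, best.start, best.end)
    return pred


class TitleExtractor:
    """End-to-end title -> metadata predictor.

    Thin predictor over a fitted :class:`BiLSTMClassifier`: gates short
    titles, preprocesses, enumerates 2-7-gram candidates, scores and
    filters them, and resolves overlaps into at most one extraction per
    category.
    """

    def __init__(self, classifier: BiLSTMClassifier, embedding: EmbeddingModel,
                 categories, stop_words=None, n_min: int = 2, n_max: int = 7,
                 eps_baseline: float = 0.01, min_in_vocab: int = 2,
                 min_margin: float = 0.1, min_words: int = 5,
                 baseline_mode: str = "argmax"):
        self.classifier = classifier
        self.embedding = embedding
        self.categories = list(categories)
        self.stop_words = default_stopwords() if stop_words is None else stop_words
        self.n_min = n_min
        self.n_max = n_max
        self.eps_baseline = eps_baseline
        self.min_in_vocab = min_in_vocab
        self.min_margin = min_margin
        self.min_words = min_words
        self.baseline_mode = baseline_mode

    def predict_title(self, title: str, sample_id: str = "") -> TitlePrediction:
        if not title_length_gate(title, self.min_words):
            return TitlePrediction(sample_id=sample_id,
                                   skipped_reason="title length gate")
        pre = preprocess_title(title, self.stop_words,
                               lowercase=self.embedding.lowercase)
        candidates = []
        for si, sent in enumerate(pre.sentences):
            candidates.extend(enumerate_ngrams(sent, self.n_min, self.n_max, si))
        survivors = score_and_filter(
            candidates, self.classifier, self.embedding, pre.sentences,
            eps_baseline=self.eps_baseline, min_in_vocab=self.min_in_vocab,
            min_margin=self.min_margin, baseline_mode=self.baseline_mode)
        return resolve_overlaps(survivors, self.categories, sample_id)

    def predict_titles(self, titles) -> list[TitlePrediction]:
        """Predict a sequence of (sample_id, title) pairs."""
        return [self.predict_title(t, sid) for sid, t in titles]


def write_predictions(path, predictions) -> None:
    """Predictions TSV: sample_id, category, text, score, span."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id\tcategory\textracted_text\tscore\t"
                 "span_start\tspan_end\tsentence_index\n")
        for pred in predictions:
            for cat, ext in sorted(pred.extractions.items()):
                fh.write(f"{pred.sample_id}\t{cat}\t{ext.text}\t{ext.score:.6f}"
                         f"\t{ext.start}\t{ext.end}\t{ext.sentence_index}\n")
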