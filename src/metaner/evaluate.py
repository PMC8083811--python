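"""Fuzzy evaluation of extracted metadata against ground-truth values.

Exact string matching is too stringent for repository metadata, so a
prediction counts as correct when either string contains the other
(case-insensitive, whitespace-normalized) or the cosine similarity of
their phrase vectors reaches 0.7.  The per-category report mirrors the
(#titles, #predicted, #correct, accuracy) accounting, with accuracy
undefined (NaN) for categories that made no prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .embedding import EmbeddingModel, cosine
from .ner import title_length_gate
from .text import tokenize

__all__ = ["MatchResult", "is_match", "select_eval_titles",
           "evaluate_predictions"]


@dataclass
class MatchResult:
    predicted: str
    truth: str
    matched: bool
    method: str  # "substring" | "cosine" | "none"
    cosine_value: float | None = None


def _normalize(s: str) -> str:
    return " ".join(s.lower().split())


def is_match(predicted: str, truth: str, model: EmbeddingModel | None = None,
             cos_threshold: float = 0.7) -> MatchResult:
    """Substring-or-cosine match between a prediction and a truth value.

    Containment is checked first on normalized strings, in both
    directions, so exact equality always matches regardless of
    embedding availability.  Otherwise the phrase-vector cosine is
    compared against *cos_threshold*; when either phrase has no
    in-vocabulary token, containment is the only path.
    """
    if not predicted or not truth:
        raise ValueError("is_match requires two non-empty strings")
    p, t = _normalize(predicted), _normalize(truth)
    cos_val = None
    if model is not None:
        pv = model.phrase_vector(tokenize(predicted, lowercase=model.lowercase))
        tv = model.phrase_vector(tokenize(truth, lowercase=model.lowercase))
        if pv is not None and tv is not None:
            cos_val = cosine(pv.components, tv.components)
    if p in t or t in p:
        return MatchResult(predicted, truth, True, "substring", cos_val)
    if cos_val is not None and cos_val >= cos_threshold:
        return MatchResult(predicted, truth, True, "cosine", cos_val)
    return MatchResult(predicted, truth, False, "none", cos_val)


def select_eval_titles(titles, truths, category, n_max: int = 1000,
                       min_words: int = 5, seed: int | None = 0,
                       exclude_studies=frozenset(),
                       title_studies=None) -> list[str]:
    """Sample up to *n_max* evaluation titles for one category.

    *titles* maps sample_id -> title text; *truths* maps
    (sample_id, category) -> ground-truth value.  Eligible titles pass
    the word-count gate, carry an annotation for *category*, and do not
    belong to an excluded (training/testing) study — pass
    *title_studies* (sample_id -> study_id) to enforce that
    disjointness.  When fewer than *n_max* titles are eligible, all are
    kept.
    """
    eligible = []
    for sid in sorted(titles):
        if (sid, category) not in truths:
            continue
        if not title_length_gate(titles[sid], min_words):
            continue
        if title_studies is not None and title_studies.get(sid) in exclude_studies:
            continue
        eligible.append(sid)
    if len(eligible) <= n_max:
        return eligible
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=n_max, replace=False)
    return [eligible[i] for i in sorted(idx)]


def evaluate_predictions(predictions, truths, model: EmbeddingModel | None,
                         categories, eval_titles: dict[str, list[str]] | None = None,
                         cos_threshold: float = 0.7):
    """Per-category (#titles, #predicted, #correct, accuracy) report.

    *predictions* is a list of TitlePrediction; *truths* maps
    (sample_id, category) -> truth string.  ``accuracy`` is
    100 x n_correct / n_predicted, NaN when the category produced no
    prediction.  A per-pair match log and a ``unigram_truth_errors``
    column (incorrect predictions whose truth is a single token) are
    included for error analysis.

    Returns ``(report_frame, match_log_frame)``.
    """
    preds_by_sample = {p.sample_id: p for p in predictions}
    rows = []
    log = []
    for cat in categories:
        if eval_titles is not None:
            sample_ids = eval_titles.get(cat, [])
        else:
            sample_ids = [sid for (sid, c) in truths if c == cat
                          and sid in preds_by_sample]
        n_titles = len(sample_ids)
        n_predicted = n_correct = n_unigram_err = 0
        for sid in sample_ids:
            pred = preds_by_sample.get(sid)
            ext = pred.extractions.get(cat) if pred is not None else None
            if ext is None:
                continue
            n_predicted += 1
            truth = truths[(sid, cat)]
            result = is_match(ext.text, truth, model, cos_threshold)
            if result.matched:
                n_correct += 1
            elif len(tokenize(truth)) == 1:
                n_unigram_err += 1
            log.append((sid, cat, ext.text, truth, result.method,
                        result.cosine_value))
        accuracy = 100.0 * n_correct / n_predicted if n_predicted else np.nan
        rows.append((cat, n_titles, n_predicted, n_correct, accuracy,
                     n_unigram_err))
    report = pd.DataFrame(
        rows, columns=["category", "n_titles", "n_predicted", "n_correct",
                       "accuracy", "unigram_truth_errors"])
    match_log = pd.DataFrame(
        log, columns=["sample_id", "category", "predicted", "truth",
                      "method", "cosine"])
    return report, match_log


def format_report(report: pd.DataFrame) -> str:
    """Render the report with N/A for undefined accuracies."""
    out = report.copy()
    out["accuracy"] = [
        "N/A" if np.isnan(a) else f"{a:.2f}" for a in report["accuracy"]]
    return out.to_string(index=False)
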