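"""Synthetic fixtures: toy embeddings, metadata corpora and titles with
planted spans.

Real inputs to the pipeline are a multi-million-pair repository
metadata dump and a pre-trained biomedical embedding; neither is needed
to exercise the method.  The generators here build a geometric
miniature of that world: each metadata category gets a tight cluster of
word vectors around a random unit centroid (intra-category pairwise
cosine above a floor, inter-category centroid cosine below a ceiling),
plus a near-isotropic background vocabulary.  Attribute-name variants,
study/sample structure and ground-truth spans planted into generated
titles make every stage's recovery measurable.

Cluster construction uses rejection sampling with an explicit audit
pass; the audit doubles as a test.  Background words share no tokens
with category vocabularies so failures are attributable.  Everything is
deterministic under the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .embedding import EmbeddingModel
from .io import AttributeValueRecord

__all__ = ["FixtureSpec", "TitleFixture", "make_toy_embedding",
           "make_records", "make_titles", "audit_embedding",
           "span_recovery_rate", "DEFAULT_CATEGORY_NAMES"]

DEFAULT_CATEGORY_NAMES = ("tissue", "cell type", "disease", "genotype",
                          "platform", "species")


@dataclass
class FixtureSpec:
    """Parameters of the synthetic world.

    The defaults are the standard desk-scale fixture used throughout
    the test suite: 6 categories x 50 words in 50 dimensions with
    intra-cluster cosine >= 0.9 and inter-cluster centroid cosine
    <= 0.3, 25 studies x 17 samples (one value per category per sample,
    ~2500 phrases, splitting 4:1 into roughly 2000 train / 500 test),
    and 4 attribute-name variants per category in proportions
    0.4/0.3/0.2/0.1.
    """

    n_categories: int = 6
    words_per_category: int = 50
    background_words: int = 100
    dim: int = 50
    intra_cluster_cosine_min: float = 0.9
    inter_cluster_cosine_max: float = 0.3
    n_studies: int = 25
    samples_per_study: int = 17
    variant_proportions: tuple = (0.4, 0.3, 0.2, 0.1)
    n_titles: int = 200
    min_planted: int = 1
    max_planted: int = 3
    delimiter_prob: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_categories, self.words_per_category,
                  self.background_words, self.dim, self.n_studies,
                  self.samples_per_study, self.n_titles)
        if any(c <= 0 for c in counts):
            raise ValueError("all fixture counts must be positive")
        lo, hi = self.intra_cluster_cosine_min, self.inter_cluster_cosine_max
        if not (0 < hi < lo < 1):
            raise ValueError(
                "cosine bounds must satisfy 0 < inter_max < intra_min < 1")
        if abs(sum(self.variant_proportions) - 1.0) > 1e-9:
            raise ValueError("variant proportions must sum to 1")

    # -- naming conventions ----------------------------------------------

    def category_names(self) -> list[str]:
        names = list(DEFAULT_CATEGORY_NAMES[: self.n_categories])
        for k in range(len(names), self.n_categories):
            names.append(f"category{k}")
        return names

    def attribute_variants(self, category: str) -> list[str]:
        """Case/punctuation variants of a category's attribute name."""
        variants = [category,
                    category.replace(" ", "_"),
                    category.title(),
                    category.upper().replace(" ", "-")]
        out = []
        for v in variants:  # dedupe single-word collisions, keep order
            if v not in out:
                out.append(v)
        return out[: len(self.variant_proportions)]

    def seeds(self) -> dict[str, str]:
        """category -> seed attribute (the canonical lowercase variant)."""
        return {cat: self.attribute_variants(cat)[0]
                for cat in self.category_names()}

    def category_word(self, k: int, i: int) -> str:
        return f"c{k}w{i:02d}"


@dataclass
class TitleFixture:
    """One generated title with its planted ground-truth spans."""

    sample_id: str
    title: str
    planted: list[tuple[str, str]] = field(default_factory=list)  # (category, phrase)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def audit_embedding(model: EmbeddingModel, spec: FixtureSpec) -> dict:
    """Exhaustive pairwise cosine audit of a toy embedding.

    Returns the empirical minimum intra-category pairwise cosine and
    maximum inter-category centroid cosine.
    """
    mins, centroids = [], []
    for k in range(spec.n_categories):
        rows = np.array([model.lookup(spec.category_word(k, i))
                         for i in range(spec.words_per_category)])
        normed = rows / np.linalg.norm(rows, axis=1, keepdims=True)
        gram = normed @ normed.T
        iu = np.triu_indices(len(rows), k=1)
        mins.append(float(gram[iu].min()))
        centroids.append(_unit(rows.mean(axis=0)))
    centroids = np.array(centroids)
    gram = centroids @ centroids.T
    iu = np.triu_indices(len(centroids), k=1)
    return {
        "min_intra_cosine": min(mins),
        "max_inter_centroid_cosine": float(np.abs(gram[iu]).max()),
    }


def make_toy_embedding(spec: FixtureSpec, max_retries: int = 50) -> EmbeddingModel:
    """Category-clustered toy embedding with isotropic background words.

    Each category's words are unit vectors drawn around a random unit
    centroid with a dispersion targeting the intra-cluster cosine
    floor; categories are resampled until the audited constraints hold
    (bounded retries).
    """
    rng = np.random.default_rng(spec.seed)
    d = spec.dim
    # dispersion: cos between two words ~ 1/(1+sigma^2); halve for slack
    sigma = 0.5 * np.sqrt(1.0 / spec.intra_cluster_cosine_min - 1.0)

    centroids = []
    for _ in range(spec.n_categories):
        for _attempt in range(max_retries):
            c = _unit(rng.standard_normal(d))
            if all(abs(float(c @ other)) <= spec.inter_cluster_cosine_max
                   for other in centroids):
                centroids.append(c)
                break
        else:
            raise RuntimeError(
                f"could not place {spec.n_categories} centroids with "
                f"inter-cosine <= {spec.inter_cluster_cosine_max} in "
                f"dim {d} within {max_retries} retries")

    vocab: dict[str, int] = {}
    vectors = []

    def _add(token, vec):
        vocab[token] = len(vectors)
        vectors.append(vec)

    for k, c in enumerate(centroids):
        for _attempt in range(max_retries):
            words = np.array([
                _unit(c + sigma * _unit(rng.standard_normal(d)))
                for _ in range(spec.words_per_category)])
            normed = words  # already unit
            gram = normed @ normed.T
            iu = np.triu_indices(len(words), k=1)
            if gram[iu].min() >= spec.intra_cluster_cosine_min:
                break
        else:
            raise RuntimeError(
                f"category {k}: intra-cluster cosine floor "
                f"{spec.intra_cluster_cosine_min} unreachable with "
                f"dispersion {sigma:.3f} (min achieved {gram[iu].min():.3f})")
        for i in range(spec.words_per_category):
            _add(spec.category_word(k, i), words[i])

    for i in range(spec.background_words):
        _add(f"bg{i:03d}", _unit(rng.standard_normal(d)))

    model = EmbeddingModel(vocab, np.array(vectors), lowercase=True)
    audit = audit_embedding(model, spec)
    if (audit["min_intra_cosine"] < spec.intra_cluster_cosine_min
            or audit["max_inter_centroid_cosine"] > spec.inter_cluster_cosine_max):
        raise RuntimeError(f"toy embedding failed its audit: {audit}")
    return model


def make_records(spec: FixtureSpec, model: EmbeddingModel | None = None):
    """Synthetic attribute-value corpus with hidden category truth.

    Every sample in every study receives one value per category: 2-7
    distinct tokens from that category's vocabulary, filed under an
    attribute-name variant drawn with the spec's proportions.  Returns
    ``(records, attribute_truth)`` where ``attribute_truth`` maps each
    variant to its category.
    """
    rng = np.random.default_rng(spec.seed + 1)
    categories = spec.category_names()
    variants = {cat: spec.attribute_variants(cat) for cat in categories}
    attribute_truth = {v: cat for cat in categories for v in variants[cat]}
    records: list[AttributeValueRecord] = []
    for j in range(spec.n_studies):
        study = f"ST{j:03d}"
        for s in range(spec.samples_per_study):
            sample = f"S{j:03d}_{s:03d}"
            for k, cat in enumerate(categories):
                n_tok = int(rng.integers(2, 8))
                word_ids = rng.choice(spec.words_per_category,
                                      size=min(n_tok, spec.words_per_category),
                                      replace=False)
                value = " ".join(spec.category_word(k, int(i)) for i in word_ids)
                props = np.asarray(spec.variant_proportions[: len(variants[cat])])
                props = props / props.sum()
                attr = variants[cat][int(rng.choice(len(props), p=props))]
                records.append(AttributeValueRecord(sample, study, attr, value))
    return records, attribute_truth


def make_titles(spec: FixtureSpec, model: EmbeddingModel | None = None):
    """Titles with 1-3 planted category phrases among background tokens.

    Each title interleaves background tokens with phrases of 2-4 tokens
    drawn from distinct categories' vocabularies; sentence delimiters
    are optionally injected between items and never inside a planted
    phrase.  Every title clears the >5-word gate by construction.
    """
    rng = np.random.default_rng(spec.seed + 2)
    categories = spec.category_names()
    fixtures: list[TitleFixture] = []
    for i in range(spec.n_titles):
        n_planted = int(rng.integers(spec.min_planted, spec.max_planted + 1))
        cats = rng.choice(spec.n_categories, size=n_planted, replace=False)
        items: list[tuple[str | None, list[str]]] = []
        planted = []
        for k in cats:
            n_tok = int(rng.integers(2, 5))
            word_ids = rng.choice(spec.words_per_category, size=n_tok,
                                  replace=False)
            phrase = [spec.category_word(int(k), int(w)) for w in word_ids]
            items.append((categories[int(k)], phrase))
            planted.append((categories[int(k)], " ".join(phrase)))
        n_planted_tokens = sum(len(ph) for _, ph in items)
        n_bg = int(rng.integers(4, 9))
        n_bg = max(n_bg, 6 - n_planted_tokens)  # always clear the >5-word gate
        for b in rng.choice(spec.background_words, size=n_bg, replace=False):
            items.append((None, [f"bg{int(b):03d}"]))
        order = rng.permutation(len(items))
        words = []
        for pos, idx in enumerate(order):
            words.extend(items[int(idx)][1])
            if pos < len(order) - 1 and rng.random() < spec.delimiter_prob:
                words[-1] += rng.choice([",", ";"])
        fixtures.append(TitleFixture(f"T{i:04d}", " ".join(words), planted))
    return fixtures


def span_recovery_rate(predictions, title_fixtures) -> float:
    """Fraction of planted spans recovered with the correct category.

    A planted span counts as recovered when the title's extraction for
    that category shares at least one token with the planted phrase
    (sub- and super-spans of the planted phrase count; a span extracted
    elsewhere in the title under the same category does not, because
    background and category vocabularies are disjoint by construction
    only across categories, not within a title's planted phrase).
    """
    preds = {p.sample_id: p for p in predictions}
    n_planted = n_recovered = 0
    for fx in title_fixtures:
        pred = preds.get(fx.sample_id)
        for cat, phrase in fx.planted:
            n_planted += 1
            if pred is None:
                continue
            ext = pred.extractions.get(cat)
            if ext is None:
                continue
            if set(ext.text.split()) & set(phrase.split()):
                n_recovered += 1
    if n_planted == 0:
        raise ValueError("no planted spans to score")
    return n_recovered / n_planted
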