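"""Training-corpus construction: length filter, caps, study-disjoint split.

The harmonized records are turned into a short-phrase classification
corpus in a frozen order: value-length filter (2-7 tokens), per-study
sample cap (100), per-category example cap (20 000), then a 4:1
train/test split that keeps every study entirely on one side.  Each
step's subsampling is uniform without replacement and reproducible
under the run seed, so the same records and seed always yield a
byte-identical corpus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .embedding import EmbeddingModel
from .text import tokenize

__all__ = [
    "TrainingExample",
    "CorpusSplit",
    "filter_by_length",
    "cap_by_study",
    "cap_by_category",
    "split_by_study",
    "encode",
    "decode",
    "build_corpus",
    "PAD_ID",
]

PAD_ID = 0  # reserved padding index; embedding row 0 is all-zero


@dataclass
class TrainingExample:
    """One encoded short phrase with its category label and provenance."""

    token_ids: np.ndarray  # length max_len, PAD_ID right-padding
    label: int
    study_id: str
    raw_value: str


@dataclass
class CorpusSplit:
    """Study-disjoint train/test partition of the encoded corpus."""

    train: list[TrainingExample]
    test: list[TrainingExample]
    categories: list[str]
    ratio: float = 0.8
    seed: int | None = None

    def arrays(self, subset: str = "train") -> tuple[np.ndarray, np.ndarray]:
        examples = self.train if subset == "train" else self.test
        X = np.stack([ex.token_ids for ex in examples])
        y = np.array([ex.label for ex in examples], dtype=np.int64)
        return X, y


def value_token_count(value: str) -> int:
    """Token count used by the length filter (vocabulary-independent)."""
    return len(tokenize(value))


def filter_by_length(records, n_min: int = 2, n_max: int = 7):
    """Keep records whose value has between *n_min* and *n_max* tokens."""
    return [r for r in records if n_min <= value_token_count(r.value) <= n_max]


def cap_by_study(records, cap: int = 100, seed: int | None = 0):
    """Limit every study to at most *cap* contributing samples.

    Sample selection is uniform without replacement over the study's
    distinct sample ids; all records of a selected sample are kept.
    """
    rng = np.random.default_rng(seed)
    by_study: dict[str, list] = {}
    for rec in records:
        by_study.setdefault(rec.study_id, []).append(rec)
    kept = []
    for study in sorted(by_study):
        recs = by_study[study]
        samples = sorted({r.sample_id for r in recs})
        if len(samples) > cap:
            idx = rng.choice(len(samples), size=cap, replace=False)
            chosen = {samples[i] for i in idx}
            recs = [r for r in recs if r.sample_id in chosen]
        kept.extend(recs)
    return kept


def cap_by_category(records, cap: int = 20_000, seed: int | None = 0):
    """Limit every category to at most *cap* examples (uniform subsample).

    Applied after the study cap; the attribute field of the records is
    expected to hold the merged category name.
    """
    rng = np.random.default_rng(seed)
    by_cat: dict[str, list] = {}
    for rec in records:
        by_cat.setdefault(rec.attribute, []).append(rec)
    kept = []
    for cat in sorted(by_cat):
        recs = by_cat[cat]
        if len(recs) > cap:
            idx = rng.choice(len(recs), size=cap, replace=False)
            recs = [recs[i] for i in sorted(idx)]
        kept.extend(recs)
    return kept


def split_by_study(records, ratio: float = 0.8, seed: int | None = 0):
    """Partition records into train/test with study-level disjointness.

    Studies are shuffled under *seed* and assigned to the training side
    until its example count first reaches *ratio* of the total; the
    remaining studies form the test side.  A single-study input cannot
    be split and is an error.

    Returns ``(train_records, test_records, train_studies, test_studies)``.
    """
    by_study: dict[str, list] = {}
    for rec in records:
        by_study.setdefault(rec.study_id, []).append(rec)
    studies = sorted(by_study)
    if len(studies) < 2:
        raise ValueError("cannot split by study: need at least 2 studies")
    rng = np.random.default_rng(seed)
    order = [studies[i] for i in rng.permutation(len(studies))]
    total = len(records)
    train_studies: list[str] = []
    count = 0
    it = iter(order)
    for study in it:
        train_studies.append(study)
        count += len(by_study[study])
        if count >= ratio * total:
            break
    test_studies = [s for s in order if s not in set(train_studies)]
    if not test_studies:  # ratio reached only with every study: hold the last out
        test_studies = [train_studies.pop()]
    train = [r for s in train_studies for r in by_study[s]]
    test = [r for s in test_studies for r in by_study[s]]
    return train, test, set(train_studies), set(test_studies)


def encode(value: str, model: EmbeddingModel, max_len: int = 7) -> np.ndarray:
    """Encode a value as right-padded embedding ids (1-based; 0 = pad).

    Out-of-vocabulary tokens are dropped; the id of an in-vocabulary
    token is its embedding row index plus one, keeping 0 reserved for
    padding.
    """
    ids = []
    for tok in tokenize(value, lowercase=model.lowercase):
        idx = model.index(tok)
        if idx is not None:
            ids.append(idx + 1)
        if len(ids) == max_len:
            break
    out = np.full(max_len, PAD_ID, dtype=np.int64)
    out[: len(ids)] = ids
    return out


def decode(token_ids, model: EmbeddingModel) -> list[str]:
    """Inverse of :func:`encode` on the in-vocabulary token subsequence."""
    return [model.token(int(i) - 1) for i in token_ids if int(i) != PAD_ID]


def build_corpus(
    harmonized_records,
    model: EmbeddingModel,
    categories: list[str],
    max_len: int = 7,
    study_cap: int = 100,
    category_cap: int = 20_000,
    ratio: float = 0.8,
    seed: int | None = 0,
) -> CorpusSplit:
    """Run the full frozen pipeline and encode the result.

    Records must already carry category names in their attribute field
    (see :func:`metaner.harmonize.harmonize_records`).  Examples with
    fewer than 2 in-vocabulary tokens after encoding are kept — the
    length filter is deliberately vocabulary-independent.
    """
    cat_index = {c: i for i, c in enumerate(categories)}
    records = [r for r in harmonized_records if r.attribute in cat_index]
    records = filter_by_length(records, 2, max_len)
    records = cap_by_study(records, cap=study_cap, seed=seed)
    records = cap_by_category(records, cap=category_cap, seed=seed)
    train_recs, test_recs, _, _ = split_by_study(records, ratio=ratio, seed=seed)

    def _examples(recs):
        return [
            TrainingExample(
                token_ids=encode(r.value, model, max_len),
                label=cat_index[r.attribute],
                study_id=r.study_id,
                raw_value=r.value,
            )
            for r in recs
        ]

    return CorpusSplit(_examples(train_recs), _examples(test_recs),
                       list(categories), ratio=ratio, seed=seed)


def write_corpus(path, split: CorpusSplit) -> None:
    """Serialize the corpus as TSV (raw_value, category, study_id, split)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# categories: {','.join(split.categories)}\n")
        fh.write(f"# ratio: {split.ratio}\n# seed: {split.seed}\n")
        fh.write("raw_value\tcategory\tstudy_id\tsplit\n")
        for name, examples in (("train", split.train), ("test", split.test)):
            for ex in examples:
                fh.write(f"{ex.raw_value}\t{split.categories[ex.label]}"
                         f"\t{ex.study_id}\t{name}\n")
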