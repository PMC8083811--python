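"""Attribute harmonization: merge raw attribute-name variants into categories.

Submitters name the same concept many ways (``cell type``, ``cell_type``,
``Cell Type``).  Rather than string-matching the names, each frequent
attribute is profiled by the mean embedding of a random sample of its
*values*; attributes whose value profiles lie within a cosine threshold
of a category's seed attribute are merged into that category.  The
merged categories become the labels of the phrase classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml
from sklearn.base import BaseEstimator

from .embedding import EmbeddingModel, cosine
from .io import AttributeValueRecord
from .text import tokenize

__all__ = [
    "AttributeProfile",
    "CategorySchema",
    "profile_attributes",
    "merge_attributes",
    "harmonize_records",
    "AttributeMerger",
    "write_schema",
    "read_schema",
]


@dataclass
class AttributeProfile:
    """Mean value-embedding profile of one raw attribute."""

    attribute: str
    occurrence_count: int
    sampled_values: list[str]
    mean_vector: np.ndarray | None  # None when every sampled value is OOV
    n_embedded_values: int = 0

    @property
    def embeddable(self) -> bool:
        return self.mean_vector is not None


@dataclass
class CategorySchema:
    """Raw attribute -> merged category mapping.

    ``members`` maps every merged raw attribute (seeds included, at
    similarity 1.0) to its category; ``similarity`` records the cosine
    to the assigned seed's profile.
    """

    categories: list[str]
    seed_attributes: dict[str, str]  # category -> seed attribute
    members: dict[str, str] = field(default_factory=dict)
    similarity: dict[str, float] = field(default_factory=dict)
    threshold: float = 0.8

    def category_index(self, category: str) -> int:
        return self.categories.index(category)

    def assign(self, attribute: str) -> str | None:
        """Category of a raw attribute, or None when unmerged."""
        return self.members.get(attribute)


def profile_attributes(
    records,
    model: EmbeddingModel,
    min_frequency: int = 100,
    n_sample: int = 100,
    seed: int | None = 0,
) -> list[AttributeProfile]:
    """Profile every attribute occurring at least *min_frequency* times.

    For each such attribute, up to *n_sample* values are drawn without
    replacement (reproducibly under *seed*), each value is embedded as
    its phrase vector, and the profile vector is the mean over the
    embedded values (equal weight per value).  Values with no
    in-vocabulary token are excluded; an attribute whose sampled values
    are all out of vocabulary is flagged unembeddable with a warning.
    """
    rng = np.random.default_rng(seed)
    by_attr: dict[str, list[str]] = {}
    for rec in records:
        by_attr.setdefault(rec.attribute, []).append(rec.value)
    profiles: list[AttributeProfile] = []
    for attr in sorted(by_attr):
        values = by_attr[attr]
        count = len(values)
        if count < min_frequency:
            continue
        if count > n_sample:
            idx = rng.choice(count, size=n_sample, replace=False)
            sampled = [values[i] for i in sorted(idx)]
        else:
            sampled = list(values)
        vecs = []
        for v in sampled:
            pv = model.phrase_vector(tokenize(v, lowercase=model.lowercase))
            if pv is not None:
                vecs.append(pv.components)
        if vecs:
            mean_vec = np.mean(vecs, axis=0)
        else:
            mean_vec = None
            warnings.warn(
                f"attribute {attr!r}: all sampled values are out of vocabulary; "
                "excluded from merging"
            )
        profiles.append(AttributeProfile(attr, count, sampled, mean_vec, len(vecs)))
    return profiles


def merge_attributes(
    profiles,
    seeds: dict[str, str],
    threshold: float = 0.8,
) -> CategorySchema:
    """Assign each profiled attribute to its most-similar seed category.

    A non-seed attribute joins the category of the seed with maximal
    cosine among seeds at or above *threshold*; attributes below the
    threshold for every seed stay unassigned.  Ties go to the earlier
    category in the schema's category order.  Each seed attribute is a
    member of its own category at similarity 1.0.
    """
    categories = list(seeds)
    by_name = {p.attribute: p for p in profiles}
    seed_vectors: dict[str, np.ndarray] = {}
    for cat, seed_attr in seeds.items():
        prof = by_name.get(seed_attr)
        if prof is None or not prof.embeddable:
            raise ValueError(
                f"seed attribute {seed_attr!r} for category {cat!r} has no "
                "embeddable profile"
            )
        seed_vectors[cat] = prof.mean_vector
    schema = CategorySchema(categories, dict(seeds), threshold=threshold)
    seed_names = set(seeds.values())
    for cat, seed_attr in seeds.items():
        schema.members[seed_attr] = cat
        schema.similarity[seed_attr] = 1.0
    for prof in profiles:
        if prof.attribute in seed_names or not prof.embeddable:
            continue
        best_cat, best_sim = None, -np.inf
        for cat in categories:  # order fixes ties
            sim = cosine(prof.mean_vector, seed_vectors[cat])
            if sim >= threshold and sim > best_sim:
                best_cat, best_sim = cat, sim
        if best_cat is not None:
            schema.members[prof.attribute] = best_cat
            schema.similarity[prof.attribute] = best_sim
    return schema


def harmonize_records(records, schema: CategorySchema) -> list[AttributeValueRecord]:
    """Relabel records with their merged category; drop unmerged attributes."""
    out = []
    for rec in records:
        cat = schema.assign(rec.attribute)
        if cat is not None:
            out.append(AttributeValueRecord(rec.sample_id, rec.study_id, cat, rec.value))
    return out


class AttributeMerger(BaseEstimator):
    """Merge raw attributes into categories by value-embedding similarity.

    scikit-learn-style estimator: ``fit`` profiles the attributes of a
    record sequence and builds the category schema; ``transform``
    relabels records with their merged category, dropping records whose
    attribute stayed unmerged.

    Parameters
    ----------
    embedding : EmbeddingModel
        Pre-trained word embedding used to vectorize sampled values.
    seeds : dict
        category name -> seed attribute name, in category order.
    threshold : float, default 0.8
        Cosine cutoff for merging an attribute into a seed's category.
    min_frequency : int, default 100
        Minimum occurrence count for an attribute to be profiled.
    n_sample : int, default 100
        Number of values sampled per attribute for profiling.
    random_state : int, default 0
        Seed for the value sampling.

    Attributes
    ----------
    profiles_ : list of AttributeProfile
    schema_ : CategorySchema
    """

    def __init__(self, embedding=None, seeds=None, threshold=0.8,
                 min_frequency=100, n_sample=100, random_state=0):
        self.embedding = embedding
        self.seeds = seeds
        self.threshold = threshold
        self.min_frequency = min_frequency
        self.n_sample = n_sample
        self.random_state = random_state

    def fit(self, X, y=None):
        if self.embedding is None or self.seeds is None:
            raise ValueError("AttributeMerger requires an embedding and seeds")
        self.profiles_ = profile_attributes(
            X, self.embedding, min_frequency=self.min_frequency,
            n_sample=self.n_sample, seed=self.random_state,
        )
        self.schema_ = merge_attributes(self.profiles_, self.seeds, self.threshold)
        return self

    def transform(self, X):
        if not hasattr(self, "schema_"):
            raise RuntimeError("AttributeMerger is not fitted")
        return harmonize_records(X, self.schema_)

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)


# ---------------------------------------------------------------------------
# serialization: TSV body + YAML comment header

def write_schema(path, schema: CategorySchema, min_frequency: int | None = None,
                 seed: int | None = None) -> None:
    meta = {
        "categories": schema.categories,
        "seed_attributes": schema.seed_attributes,
        "threshold": schema.threshold,
    }
    if min_frequency is not None:
        meta["min_frequency"] = min_frequency
    if seed is not None:
        meta["seed"] = seed
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in yaml.safe_dump(meta, sort_keys=False).splitlines():
            fh.write(f"# {line}\n")
        fh.write("attribute\tcategory\tsimilarity\n")
        for attr in sorted(schema.members):
            fh.write(f"{attr}\t{schema.members[attr]}\t{schema.similarity[attr]:.6f}\n")


def read_schema(path) -> CategorySchema:
    header_lines, rows = [], []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("# "):
                header_lines.append(line[2:])
            elif line.strip() and not line.startswith("attribute\t"):
                rows.append(line.rstrip("\n").split("\t"))
    meta = yaml.safe_load("".join(header_lines))
    schema = CategorySchema(
        categories=list(meta["categories"]),
        seed_attributes=dict(meta["seed_attributes"]),
        threshold=float(meta["threshold"]),
    )
    for attr, cat, sim in rows:
        schema.members[attr] = cat
        schema.similarity[attr] = float(sim)
    return schema
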