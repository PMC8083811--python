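# metaner

**Named-entity recognition for sample metadata.** Public sequencing
repositories store sample annotations as attribute–value pairs
(`tissue → liver`), but most samples are missing values for most
attributes, and submitters name the same concept in many inconsistent
ways (`cell type`, `cell_type`, `Cell Type`). `metaner` implements a
fully automated pipeline that imputes missing metadata from the one
free-text field most samples do have — the sample TITLE:

1. **Attribute harmonization.** Every frequent attribute is profiled by
   the mean word-embedding vector of a random sample of its values;
   attributes whose profiles have cosine similarity ≥ 0.8 to a
   category's seed attribute are merged into that category. The merged
   categories (Age, Cell type, Condition/Disease, …) become classifier
   labels.
2. **Short-phrase classification.** A bidirectional LSTM (embedding
   layer over pre-trained word vectors → 64 units per direction,
   input dropout 0.5 → dense logistic outputs, one sigmoid score per
   category) is trained for a single epoch of Adam (batch 100,
   lr 0.001) on values of 2–7 tokens, with a 100-sample cap per study,
   a 20 000-example cap per category, and a 4:1 train/test split that
   keeps every study on one side.
3. **N-gram extraction.** Each title (> 5 words) is split into
   sentences on `; , .`, tokenized and stop-word-filtered; every
   2–7-gram is scored by the classifier. Candidates survive only if
   they have ≥ 2 in-vocabulary tokens, score more than 0.01 away from
   the empty-string baseline, and beat the runner-up category by more
   than 0.1; overlapping same-category spans keep the best scorer, and
   each category yields at most one extraction per title.
4. **Fuzzy evaluation.** A prediction matches its ground truth when
   either string contains the other (case-insensitive) or their
   phrase-vector cosine is ≥ 0.7; per-category reports count
   #titles / #predicted / #correct with accuracy = correct/predicted.

The package targets curators and computational biologists who want to
increase metadata coverage of repository samples without manual
curation, and anyone studying embedding-based harmonization of noisy
attribute–value metadata. It is written as scikit-learn-style
estimators (`AttributeMerger`, `BiLSTMClassifier`) plus a thin
`TitleExtractor` predictor and a `metaner` command-line interface. The
recurrent network is implemented in pure numpy (forward pass,
backpropagation through time, Adam), with gradients verified against
numerical differentiation in the test suite.

## Worked example

Everything below runs on the built-in synthetic world (no downloads):
a 50-dimensional toy embedding with 6 tight category clusters, 25
studies × 17 samples of attribute–value pairs filed under noisy
attribute-name variants, and titles with planted ground-truth spans.

```python
from metaner import (FixtureSpec, AttributeMerger, TitleExtractor, build_corpus,
                     evaluate_classifier, make_records, make_titles,
                     make_toy_embedding, train_classifier)

spec = FixtureSpec(seed=0)                      # 6 categories, 50-dim toy embedding
embedding = make_toy_embedding(spec)
records, _ = make_records(spec, embedding)      # 2550 attribute-value pairs, 25 studies

merger = AttributeMerger(embedding=embedding, seeds=spec.seeds(),
                         min_frequency=25, random_state=0).fit(records)
print(f"merged {len(merger.schema_.members)} attribute variants "
      f"into {len(merger.schema_.categories)} categories")

split = build_corpus(merger.transform(records), embedding,
                     merger.schema_.categories, seed=0)
print(f"corpus: {len(split.train)} train / {len(split.test)} test phrases")

clf = train_classifier(split, embedding, random_state=0)   # one epoch of Adam
X, y = split.arrays("test")
m = evaluate_classifier(clf, X, y, split.categories)
print(f"test accuracy {m.accuracy:.3f}, micro-average AUROC {m.micro_average_auroc:.3f}")

title = make_titles(spec, embedding)[0]
extractor = TitleExtractor(clf, embedding, split.categories)
pred = extractor.predict_title(title.title, title.sample_id)
print("title:   ", title.title)
for cat, ext in sorted(pred.extractions.items()):
    print(f"extracted {cat!r}: {ext.text!r} (score {ext.score:.2f})")
```

Output:

```
merged 19 attribute variants into 6 categories
corpus: 2040 train / 510 test phrases
test accuracy 1.000, micro-average AUROC 1.000
title:    bg063 bg041 bg064 bg091 c5w02 c5w27 c5w08 c5w42, bg095, c0w13 c0w27 bg021 c1w04 c1w16 c1w30 bg040
extracted 'cell type': 'c1w04 c1w16 c1w30' (score 0.66)
extracted 'species': 'c5w02 c5w27 c5w08 c5w42' (score 0.64)
extracted 'tissue': 'c0w13 c0w27' (score 0.64)
```

All 19 attribute-name variants merge into their true category, the
single-epoch classifier separates the held-out phrases perfectly, and
the extractor pulls each planted span out of the noisy title under its
correct category while ignoring the background tokens (`bg…`).

The same workflow is available from the shell on TSV/word2vec files:

```sh
metaner simulate --config sim.yaml --seed 0       # write a synthetic world
metaner merge-attributes --config merge.yaml      # -> schema.tsv
metaner train --config train.yaml                 # -> model.npz + metrics
metaner predict --config pred.yaml                # -> predictions.tsv
metaner evaluate --config eval.yaml               # -> Table-style report
```

Real inputs are a 4-column TSV (`sample_id  study_id  attribute
value`) and a word2vec text or binary embedding file.

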