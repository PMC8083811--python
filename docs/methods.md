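# Methods

## The pipeline and its assumptions

`metaner` treats metadata imputation as named-entity recognition with a
classifier trained on the repository's own structured metadata. The
central assumptions are:

- **Embedding geometry carries meaning.** Attribute values drawn from
  the same concept ("liver", "hepatocyte", "brain") lie close in a
  pre-trained word-embedding space, and a phrase is represented
  adequately by the unweighted mean of its token vectors.
  Out-of-vocabulary tokens are skipped, never zero-imputed; a phrase
  with no in-vocabulary token has no vector.
- **Attribute names are noise; values are signal.** Harmonization never
  embeds attribute *names* — only a random sample of their values — so
  `cell type` and `cell_type` merge because their values look alike,
  not because their names do.
- **Short phrases suffice.** The classifier sees only 2–7-token values,
  so extraction candidates are restricted to 2–7-grams. Single-token
  entities (much of Sex and Age in real data) are invisible to the
  method by construction.

## Attribute harmonization

Each attribute occurring at least `min_frequency` times is profiled by
up to `n_sample` values drawn without replacement; the profile vector
is the mean over values of each value's phrase vector (equal weight
per value, not per token — a deliberate choice so long values do not
dominate; an equal-per-token variant would weight by value length).
A non-seed attribute joins the category of the most-similar seed among
those with cosine ≥ `threshold` (default 0.8); ties go to the earlier
category in schema order. Assignment is single-category: overlapping
groups would make training labels ambiguous. Attributes below the
threshold for every seed remain unmerged and are dropped from training.

Defaults: `min_frequency=100`, `n_sample=100`, `threshold=0.8` —
appropriate for repository-scale tables with tens of millions of
pairs. The synthetic fixture (~425 records per category split over 4
name variants) uses `min_frequency=25` so that even its rarest variant
(~10% share) is profiled; this is a fixture-scale analogue of the same
rule, not a change to the method.

## Corpus construction

A frozen order: harmonize → length filter (2–7 tokens, counted
vocabulary-independently so the filter does not depend on the
embedding) → per-study cap (100 samples, against study bias) →
per-category cap (20 000 examples, against class imbalance) →
study-disjoint 4:1 split (studies shuffled under the run seed and
assigned to the training side until it first holds ≥ 80% of examples).
Order matters — the caps see only what the length filter kept — so it
is fixed and every stage is reproducible under one seed. Values are
encoded as right-padded embedding-row ids with index 0 reserved for
padding (embedding row 0 is all-zero and excluded from the
vocabulary).

## The classifier

Embedding layer (pre-trained vectors, frozen by default;
`trainable_embedding=True` lets gradient flow into them) → one
bidirectional LSTM layer, 64 hidden units per direction, input dropout
0.5 during training only → dense layer with one *logistic* unit per
category. Score vectors are independent sigmoids and do not sum to 1;
all downstream logic (margins, baselines) treats them as independent
per-category scores. Training uses categorical cross-entropy over the
sum-normalized sigmoids — i.e. the loss is
`-log(σ_true / Σ_c σ_c)` — which is how the mainstream deep-learning
frameworks interpret a categorical loss over non-softmax outputs; the
reported scores remain the raw sigmoids. One epoch of Adam
(lr 0.001, batch 100), with per-batch losses logged.

Numerical and architectural choices worth knowing:

- **Scale-aware input-kernel initialization.** Pre-trained word
  vectors are near unit norm, so their per-component variance is
  ~1/dim — far below the unit variance classical Glorot scaling
  assumes. The input kernels are therefore drawn uniform with limit
  `sqrt(3) / (s · sqrt(dim))` where `s` is the empirical per-component
  RMS of the embedding matrix, giving unit-variance gate
  preactivations. Recurrent kernels are orthogonal (per gate), the
  forget-gate bias starts at 1, and the dense head starts at zero so
  every category opens at score 0.5 and the head's first steps are
  already aligned with the recurrent features. Both choices matter
  because training is a *single* pass: a mis-scaled or randomly
  biased start cannot be walked back over multiple epochs.
- **Masked final states.** The output feature is the concatenation of
  the two directions' final states, read at the edges of the real
  tokens: the backward direction consumes trailing pads first (zero
  input leaves its state at exactly zero), and the forward state is
  gathered at the last non-padding position rather than after coasting
  through pads, which otherwise dilutes short phrases. A `mean`
  output mode (time-average of hidden states) is available.
- **Determinism.** Initialization, shuffling and dropout masks all
  derive from one `random_state`; inference disables dropout and is
  bit-reproducible. Non-finite training loss raises immediately.
- **Degenerate inputs.** The all-padding row (the "empty string")
  produces the baseline score vector used by the extractor's filter;
  with zero-initialized head it starts at exactly 0.5 per category and
  moves only through the trained biases. Ties in argmax go to the
  lowest category index.

Evaluation reports argmax accuracy, micro- and macro-averaged
precision/recall/F1, per-category one-vs-rest AUROC (undefined when a
category is absent from the test set), micro-average AUROC over the
flattened example × category score/indicator pairs (constant indicator
columns excluded), and a row-normalized confusion matrix.

## Extraction and filtering

Titles of ≤ 5 whitespace words are skipped (strictly greater than five
survives). Sentences split on `; , .`; tokens are lowercased,
edge-punctuation-trimmed, and stop words removed (a standard English
list shipped as a replaceable data file). Every 2–7-gram of every
sentence is scored. The cascade keeps a candidate iff:

1. ≥ 2 of its tokens are in the embedding vocabulary;
2. its top-category score differs from the empty-string baseline by
   more than 0.01 — compared at the assigned (argmax) category by
   default, the least destructive reading; a whole-vector mode
   (`baseline_mode="all"`) discards only candidates whose every
   component is within 0.01 of the baseline;
3. its top score beats the runner-up by strictly more than 0.1.

The filters are independent predicates, so their order (in-vocab →
baseline → margin, frozen for reproducible logs) does not affect the
surviving set. Overlap resolution is per category: among same-category
candidates sharing a token offset in the same sentence only the best
scorer survives, and if several disjoint same-category spans remain,
the single best populates the prediction — one extraction per category
per title, matching the per-title accounting of the evaluation report
(the pre-argmax retained set is kept on the prediction object for
inspection).

## Match evaluation

`is_match` checks containment first on lowercased,
whitespace-collapsed strings (both directions, so exact equality
always matches even when both strings are out of vocabulary), then the
phrase-vector cosine against the 0.7 threshold ("0.7 or more"
matches). When either side has no in-vocabulary token, containment is
the only path. Per-category rows report
`accuracy = 100 · n_correct / n_predicted`, undefined (N/A) when
nothing was predicted; a `unigram_truth_errors` column flags incorrect
predictions whose ground truth is a single token, since those are
structurally unreachable for a 2–7-gram extractor.

## The synthetic world

`FixtureSpec` defaults define the standard desk-scale fixture used by
the tests and the acceptance script: 6 categories × 50 words in 50
dimensions, intra-cluster pairwise cosine ≥ 0.9 and inter-centroid
cosine ≤ 0.3 (rejection-sampled with an explicit audit pass — the
audit doubles as a test), 100 near-isotropic background words sharing
no tokens with the clusters, 25 studies × 17 samples with one value
per category per sample (~2550 phrases splitting 4:1 into roughly
2040/510), 4 attribute-name variants per category in proportions
0.4/0.3/0.2/0.1, and 200 titles each planting 1–3 phrases of 2–4
tokens from distinct categories among 4–8 background tokens, with
sentence delimiters injected between (never inside) items.

What the fixture emulates: category-clustered value vocabularies with
a matching embedding, attribute-name noise, study/sample structure,
and titles whose entities sit among distractor tokens and sentence
delimiters. What it does not emulate: the heavy-tailed value-length
and attribute-frequency distributions of real repositories, unigram
ground truths, out-of-vocabulary tokens inside entities, semantically
*adjacent* categories (real Cell type vs Tissue overlap far more than
the fixture's ≤ 0.3 centroid cosine), and annotation disagreement
between titles and stored metadata. Passing the recovery tests
therefore demonstrates that the machinery is correct and that the
method works when its geometric premise holds — not that real-data
accuracy will match the fixture's near-perfect numbers.

Fixture recovery levels (merge recovery ≥ 95%, classifier accuracy
≥ 0.95 with micro AUROC ≥ 0.99, planted-span recovery ≥ 90%) are
artifact acceptance levels for the synthetic world, not claims about
real repositories.

## Known limitations

- No unigram extraction: entities of one token cannot be predicted.
- Harmonization is single-assignment and threshold-based; it neither
  maps to ontologies nor auto-tunes the 0.8 cutoff.
- The classifier is deliberately small and trained for one epoch as
  the method prescribes; it is not a general-purpose text classifier.
- Phrase vectors are unweighted means; no tf-idf weighting, subword
  composition or contextual embeddings.
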