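# Methods

This note documents the models, the synthetic data, the numerical choices
and the known limitations of the package. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Corpus model and text preprocessing

An article is (pmid, title, abstract, publication date, authors with raw
affiliation strings). Records lacking an abstract are kept — the title
still contributes tokens and geographic mentions — while records lacking
a PMID are rejected. A missing date is represented as missing, never
defaulted; date filters drop undated records and log the count.

Tokenization is deliberately minimal: case-fold, split on whitespace and
punctuation, keep internal hyphens and underscores, keep digits, no
stemming, no stopword removal. The downstream mechanism is window-based
co-occurrence statistics in the embedding, which is robust to function
words; a minimal tokenizer keeps the pipeline auditable and exactly
reproducible. The tokenizer is idempotent (re-tokenizing joined tokens is
a fixed point), which the suite property-tests.

## Geo-bibliometrics

Two tracks answer different questions:

* **Article mentions.** A gazetteer of country names and major city names
  is matched against title+abstract with word-boundary anchoring, longest
  surface first. Each country counts at most once per article, because
  the unit of evidence is the publication, not the repetition. City hits
  map to their country.
* **Unique authors.** Author identity is the normalized name string
  (case-folded, whitespace-collapsed, diacritics stripped). Each unique
  author contributes exactly 1 to every distinct country found across all
  their affiliation strings in the whole corpus: publishing ten papers
  from one country still counts once; holding affiliations in two
  countries counts once in each.

Ambiguous homographs (a place name that is also a common word, e.g.
"Turkey") are matched case-sensitively; all other surfaces match
case-insensitively. This trades recall for precision, which is the right
trade at country-level granularity. Continent and World Bank income-class
rollups are group-sums that conserve totals; countries absent from the
metadata route to "Unknown continent" / "Not classified" with a warning.
The income table is a versioned TSV input because the classification is
revised annually.

Known limitation: author identity by name string merges distinct authors
who share a normalized name and splits authors who change name spelling.
No disambiguation beyond normalization is attempted, and counts are not
normalized by a country's total publication output.

## Concept tagging and phrase fusion

Disease, food and microbe occurrences are found by dictionary
longest-match: greedy left-to-right over the token stream,
case-insensitive, matched tokens consumed so spans cannot overlap. On an
equal-length cross-class tie the precedence is microbe > disease > food
(species binomials are the most specific nomenclature); the order is a
parameter. Surface forms are tokenized with the corpus tokenizer so
matching is representation-consistent, and a surface assigned to two
classes is a load error.

Matched spans are then *fused*: the span's tokens are replaced by the
canonical term's underscore-joined form, so "CRC" and "colorectal cancer"
both become the single token `colorectal_cancer`. Tagging happens before
embedding so the trainer learns one vector per canonical phrase rather
than averaging member-word vectors. External taggers can be plugged in
through the TaggedSpan TSV interface, bypassing the built-in matcher.

## Skip-gram embeddings

The trainer implements skip-gram with negative sampling in a
numba-compiled kernel. Defaults: 100-dimensional vectors, 10 epochs,
initial learning rate 0.025 decaying linearly to 1e-4 over all
token-epochs, context window 5 (uniformly shrunk per position, the
standard trick that weights near context more heavily), minimum corpus
frequency 3, 5 negative samples drawn from the unigram^0.75 distribution
via a 250,000-entry table. Input vectors are initialized uniformly in
±0.5/dim from a seeded generator; output vectors start at zero; the
logistic function is clipped at |x| = 6.

Numerical/reproducibility choices:

* Single-threaded training with a seeded 64-bit LCG makes runs bitwise
  reproducible; a fixed seed is part of every model's provenance along
  with a SHA-256 fingerprint of the token stream.
* Frequent-word subsampling is disabled by default. On corpora at the
  scale exercised here it mainly adds a second stochastic pass, and
  determinism and auditability were preferred; the min-count filter and
  negative sampling already bound the influence of very frequent tokens.
* All arithmetic is float32, matching common practice and halving memory.

Cosine *distance* is defined as 1 − cosine similarity, so it lives in
[0, 2] with 0 = identical direction; the network thresholds below are
distance ceilings. A similarity-floor reading is available via a flag on
network construction for users who prefer that convention.

## Semantic networks

`build_network` enumerates all cross-class pairs among terms that have
vectors (terms below min-count are skipped and logged) and keeps edges
with distance ≤ θ. Nodes without any edge at θ are excluded by default,
so node counts grow with the threshold; `keep_isolated=True` retains the
fixed vocabulary instead. Threshold sweeps compute one all-pairs distance
matrix and bin it, guaranteeing sweep counts equal per-θ construction —
the suite asserts this equality and the nesting E(θ₁) ⊆ E(θ₂) for
θ₁ ≤ θ₂. The default grid is 0.00–1.00 in steps of 0.05; distances above
1 correspond to anti-correlated vectors and are rarely meaningful, but
custom grids up to 2 are accepted.

Coverage against a curated reference edge set separates *mappable* pairs
(both endpoints in the vocabulary) from unmappable ones — a pair whose
term never occurs in the corpus at sufficient frequency cannot be
recovered and says nothing about embedding quality. Coverage fraction at
θ is n_found/n_reference and is monotone, saturating at n_mappable. A
synonym map translates external nomenclature to corpus canonicals before
lookup. Sweep and per-term neighborhood queries break distance ties
lexicographically for determinism.

## Synthetic data: what it emulates and what it does not

The generator emulates the statistical structure the semantic pipeline
relies on, not natural language. Background tokens are drawn from a Zipf
distribution (exponent 1.1 over a 2,000-word vocabulary) so that rare
words genuinely exercise the min-count filter. A planted cross-class pair
is inserted into a document with probability `assoc_doc_fraction`, its
members 1–2 tokens apart (within the window-5 context), while stray
concept terms are inserted as isolated singletons (probability 0.1 per
document) so non-planted terms reach the vocabulary at chance-level
co-occurrence. Each abstract names one country (literal country names by
default; matching city names is deliberately left to gazetteer tests with
hand-written text), and 1–4 authors are drawn from a 40-author pool in
which 15% hold two country affiliations.

The standard study condition is 2,000 documents, 20 diseases ×
20 microbes with 30 planted edges, association fraction 0.3, mean
abstract length 120 tokens — sizes at which a single training run takes
seconds on one CPU while the planted/non-planted separation is clearly
measurable. Under it, planted pairs have strictly higher within-window
co-occurrence than any non-planted cross-class pair (asserted
empirically at n ≥ 1,000 documents), and the embedding recovers them
with mean AUROC ≥ 0.8 over three seeds.

Passing on synthetic corpora therefore shows the pipeline is correct and
the embedding exploits windowed co-occurrence as intended. It does not
show robustness to the things real abstracts add: polysemy, synonymy
outside the dictionary, section structure, negation, or correlations
between topic and geography. The 10-document fixture is hand-written to
make bibliometric counts hand-checkable (one author on three papers, one
dual-country author, a mention-only territory, a case-sensitive
homograph), not to be representative text.

## Pipelines and provenance

The two pipeline entry points compose the module operations exactly (the
suite asserts pipeline output equals direct calls). Every CSV starts with
a `# provenance:` JSON header carrying input hashes, the effective
configuration, the seed and the tool version; each run ends with a
manifest of output hashes. No output embeds wall-clock time, so identical
configurations reproduce byte-identical manifests — which is also the
determinism acceptance check.

## Degenerate inputs and tie-breaks, in one place

* Empty corpus: parsing warns and returns an empty corpus; training
  raises (no vocabulary to learn).
* Zero vectors: cosine measures raise rather than return NaN.
* θ = 0: edges require exact collinearity; with generic trained vectors
  the network is empty.
* Equal distances in rankings: lexicographic term order.
* Duplicate pmids on ingest: first record wins, warning logged.
* Tagging ties: longest match first, then class precedence, then
  canonical term order.
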