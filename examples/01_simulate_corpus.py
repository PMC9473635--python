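"""Generate a synthetic abstract corpus with planted structure.

Builds the default study condition (2,000 documents, 20 diseases,
20 microbes, 30 planted disease-microbe associations appearing in 30% of
documents) and prints what was planted. The ground truth is what later
stages are scored against.
"""

import microlit as ml

spec = ml.PlantedModel.default(n_docs=2000, seed=1)
corpus, truth = ml.generate_corpus(spec)

print(f"documents: {len(corpus)}")
print(f"planted associations: {len(truth.planted_edges)}")
print("first three planted pairs:", truth.planted_edges[:3])
print("country mention rates:",
      dict(list(truth.expected_country_article_rates.items())[:3]), "...")
rec = corpus[0]
print(f"\nsample record {rec.pmid} ({rec.pub_date}):")
print(" ", rec.abstract[:120], "...")

# Each abstract is Zipf-distributed background text; when a planted pair is
# present its two terms sit within a couple of tokens of each other, which
# is what lets a window-based embedding discover the association later.
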