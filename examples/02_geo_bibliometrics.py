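"""Country, continent and income tallies on the 10-document fixture.

Two tracks are tallied: articles *mentioning* a country in their title or
abstract (a proxy for where studies are focused) and unique *authors*
affiliated with a country (a proxy for where research activity sits).
"""

import microlit as ml

corpus = ml.fixture_corpus()
gaz = ml.Gazetteer.default()

mentions = ml.tally_articles_by_country(corpus, gaz)
authors = ml.tally_authors_by_country(corpus, gaz)

print("article mentions per country:", mentions.counts)
print("unique authors per country:  ", authors.counts)
print("mentions by continent:", ml.aggregate(mentions, "continent", gaz))
print("mentions by income:   ", ml.aggregate(mentions, "income", gaz))

table = ml.scatter_table(mentions, authors, gaz)
print("\nscatter table (article vs author counts per country):")
print(table.to_string(index=False))

# Note ATA (Antarctica): one article mentions it but no author is
# affiliated there — mention counts and researcher counts measure
# different things, and the scatter table makes such imbalances visible.
# The author tally also shows the dedup rules: one author on three papers
# counts once (JPN), and one author with affiliations in two countries
# counts once for each (USA and JPN).
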