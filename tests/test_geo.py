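"""Geo-bibliometrics: mention extraction, author dedup, rollups, scatter."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import microlit as ml

EXPECTED_MENTIONS = {"JPN": 4, "USA": 3, "CHN": 1, "MWI": 1, "ATA": 1,
                     "BRA": 1, "IND": 1}
EXPECTED_AUTHORS = {"JPN": 2, "USA": 1, "BRA": 1, "MWI": 1, "CHN": 1,
                    "IND": 1}


class TestMentionExtraction:
    def test_no_hit_gives_empty_set(self, gazetteer):
        assert ml.extract_country_mentions(
            "the gut microbiome of mice", gazetteer) == set()

    def test_repeat_mentions_count_once(self, gazetteer):
        text = "children in Malawi were enrolled; the Malawi cohort grew"
        assert ml.extract_country_mentions(text, gazetteer) == {"MWI"}

    def test_city_hits_map_to_their_countries(self, gazetteer):
        text = "samples from Boston and Shanghai"
        assert ml.extract_country_mentions(text, gazetteer) == {"USA", "CHN"}

    def test_homograph_is_case_sensitive(self, gazetteer):
        assert ml.extract_country_mentions(
            "a turkey sandwich diet", gazetteer) == set()
        assert ml.extract_country_mentions(
            "a cohort recruited in Turkey", gazetteer) == {"TUR"}

    def test_word_boundaries_respected(self, gazetteer):
        # 'Indiana' must not fire the 'India' surface form
        assert ml.extract_country_mentions(
            "a cohort from Indiana", gazetteer) == set()


class TestAffiliationMapping:
    @pytest.mark.parametrize("affiliation,expected", [
        ("Dept. of Medicine, University of Tokyo, Tokyo, Japan", {"JPN"}),
        ("SBX Corporation Inc., Tokyo, Japan", {"JPN"}),
        ("Institute of Advanced Studies", set()),
        ("Harvard University, Boston, USA", {"USA"}),
    ])
    def test_examples(self, affiliation, expected, gazetteer):
        assert ml.map_affiliation_to_countries(affiliation, gazetteer) \
            == expected


class TestTallies:
    def test_article_mentions_match_hand_count(self, fixture_corpus,
                                               gazetteer):
        tally = ml.tally_articles_by_country(fixture_corpus, gazetteer)
        assert tally.counts == EXPECTED_MENTIONS
        assert tally.kind == "article_mentions"

    def test_unique_authors_match_hand_count(self, fixture_corpus, gazetteer):
        """One author on three papers counts once; one author with
        affiliations in two countries counts once per country."""
        tally = ml.tally_authors_by_country(fixture_corpus, gazetteer)
        assert tally.counts == EXPECTED_AUTHORS

    def test_author_total_independent_of_papers_per_author(self, gazetteer):
        recs = [ml.ArticleRecord(
            pmid=str(i), title="t",
            authors=(ml.AuthorRecord("Same, Author",
                                     ("Lab, Tokyo, Japan",)),))
            for i in range(5)]
        tally = ml.tally_authors_by_country(ml.Corpus(records=recs), gazetteer)
        assert tally.counts == {"JPN": 1}

    def test_two_authors_sharing_a_country_add_up(self, gazetteer):
        rec = ml.ArticleRecord(
            pmid="1", title="t",
            authors=(ml.AuthorRecord("A, One", ("Lab, Japan",)),
                     ml.AuthorRecord("B, Two", ("Lab, Tokyo, Japan",))))
        tally = ml.tally_authors_by_country(ml.Corpus(records=[rec]),
                                            gazetteer)
        assert tally.counts == {"JPN": 2}

    def test_empty_corpus_gives_empty_tally(self, gazetteer):
        assert ml.tally_articles_by_country(ml.Corpus(), gazetteer).counts \
            == {}

    def test_synthetic_mention_rates_recover_planted_rates(self):
        """Relative country-mention frequencies on a 2,000-doc synthetic
        corpus must be consistent with the planted rates (chi-square
        goodness of fit not rejected at alpha=0.01)."""
        spec = ml.PlantedModel.default(n_docs=2000, seed=21)
        corpus, truth = ml.generate_corpus(spec)
        tally = ml.tally_articles_by_country(corpus, ml.Gazetteer.default())
        codes = sorted(truth.expected_country_article_rates)
        observed = np.array([tally.counts.get(c, 0) for c in codes])
        expected = np.array([truth.expected_country_article_rates[c]
                             for c in codes]) * observed.sum()
        assert stats.chisquare(observed, expected).pvalue >= 0.01


class TestAggregation:
    def test_continent_group_sum(self, gazetteer):
        tally = ml.CountryTally(kind="article_mentions",
                                counts={"JPN": 4, "CHN": 1})
        assert ml.aggregate(tally, "continent", gazetteer) == {"Asia": 5}

    def test_unknown_country_routed_to_not_classified(self, gazetteer):
        tally = ml.CountryTally(kind="article_mentions", counts={"XXX": 2})
        assert ml.aggregate(tally, "income", gazetteer) \
            == {"Not classified": 2}
        assert ml.aggregate(tally, "continent", gazetteer) \
            == {"Unknown continent": 2}

    @given(st.dictionaries(
        st.sampled_from(["USA", "JPN", "CHN", "BRA", "MWI", "XXX"]),
        st.integers(min_value=0, max_value=100), max_size=6))
    def test_totals_conserved_at_both_levels(self, counts):
        gaz = ml.Gazetteer.default()
        tally = ml.CountryTally(kind="article_mentions", counts=counts)
        for level in ("continent", "income"):
            assert sum(ml.aggregate(tally, level, gaz).values()) \
                == tally.total()


class TestScatterTable:
    def test_union_of_countries_with_zero_guard(self, fixture_corpus,
                                                gazetteer):
        articles = ml.tally_articles_by_country(fixture_corpus, gazetteer)
        authors = ml.tally_authors_by_country(fixture_corpus, gazetteer)
        frame = ml.scatter_table(articles, authors, gazetteer)
        assert len(frame) == len(set(articles.counts) | set(authors.counts))
        ata = frame[frame.country == "ATA"].iloc[0]
        # mirrors the many-mentions/no-local-authors imbalance
        assert ata.article_count == 1 and ata.author_count == 0
        assert np.isnan(ata.log10_authors)
        assert ata.income_class == "Not classified"

    def test_article_only_country_has_zero_author_count(self, gazetteer):
        articles = ml.CountryTally(kind="article_mentions",
                                   counts={"JPN": 3})
        authors = ml.CountryTally(kind="unique_authors", counts={})
        frame = ml.scatter_table(articles, authors, gazetteer)
        assert list(frame.country) == ["JPN"]
        assert frame.iloc[0].author_count == 0


def test_gazetteer_tsv_roundtrip(fixture_dir):
    gaz = ml.Gazetteer.from_tsv(fixture_dir / "gazetteer.tsv",
                                fixture_dir / "country_meta.tsv")
    assert gaz.find_countries("University of Tokyo, Japan") == {"JPN"}
    assert gaz.income_of("MWI") == "Low income"
    assert gaz.continent_of("BRA") == "South America"
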