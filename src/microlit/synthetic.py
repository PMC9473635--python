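"""Synthetic corpora with planted semantic and geographic structure.

Real microbiome abstracts cannot ship with the package, so every
downstream stage is exercised on generated ones. A :class:`PlantedModel`
describes the study conditions:

* background text drawn from a Zipf distribution over a synthetic
  vocabulary (so rare words genuinely exercise min-count filtering);
* *planted associations* — cross-class concept pairs (e.g. a disease and a
  microbe) inserted into a fraction of documents within a few tokens of
  each other, i.e. inside the embedding's context window;
* *stray* concept terms inserted as isolated singletons so non-planted
  terms still reach the vocabulary, at chance-level co-occurrence;
* one literal country mention per abstract, sampled from configurable
  per-country rates, plus authors drawn from a pool with one- or
  two-country affiliations.

Everything is reproducible from the model's seed, and the
:class:`GroundTruth` needed for recovery scoring is derivable from the
model without sampling.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus import (ArticleRecord, AuthorRecord, Corpus, write_corpus_tsv,
                     write_pubmed_xml)

#: country codes the default generator can name in text
CODE_TO_NAME = {
    "USA": "United States", "CHN": "China", "JPN": "Japan",
    "DEU": "Germany", "GBR": "United Kingdom", "FRA": "France",
    "CHE": "Switzerland", "BRA": "Brazil", "IND": "India",
    "MWI": "Malawi", "ZAF": "South Africa", "LUX": "Luxembourg",
    "ATA": "Antarctica", "AUS": "Australia", "CAN": "Canada",
    "ITA": "Italy", "ESP": "Spain", "KOR": "South Korea",
    "MEX": "Mexico", "NGA": "Nigeria", "KEN": "Kenya",
}

DEFAULT_COUNTRY_RATES: tuple[tuple[str, float], ...] = (
    ("USA", 0.25), ("CHN", 0.20), ("JPN", 0.10), ("DEU", 0.08),
    ("GBR", 0.08), ("BRA", 0.07), ("IND", 0.07), ("FRA", 0.06),
    ("ZAF", 0.05), ("MWI", 0.04),
)


@dataclass
class PlantedModel:
    """Full description of one synthetic-corpus condition."""

    disease_terms: tuple[str, ...]
    food_terms: tuple[str, ...]
    microbe_terms: tuple[str, ...]
    planted_edges: tuple[tuple[str, str], ...]
    assoc_doc_fraction: float = 0.3
    cooccur_gap: int = 2  # max token distance of a planted pair (<= window)
    stray_term_prob: float = 0.1
    background_vocab_size: int = 2000
    zipf_exponent: float = 1.1
    doc_length: int = 120  # mean background tokens per abstract
    n_docs: int = 2000
    countries: tuple[tuple[str, float], ...] = DEFAULT_COUNTRY_RATES
    author_pool: tuple[tuple[str, tuple[str, ...]], ...] = ()
    seed: int = 1

    def __post_init__(self) -> None:
        classes = {"disease": set(self.disease_terms),
                   "food": set(self.food_terms),
                   "microbe": set(self.microbe_terms)}
        all_terms: set[str] = set()
        for name, terms in classes.items():
            if all_terms & terms:
                raise ValueError(
                    f"concept vocabularies overlap at class {name!r}: "
                    f"{sorted(all_terms & terms)}")
            all_terms |= terms
        term_class = {t: c for c, ts in classes.items() for t in ts}
        for a, b in self.planted_edges:
            if a not in term_class or b not in term_class:
                raise ValueError(f"planted edge ({a!r}, {b!r}) uses unknown terms")
            if term_class[a] == term_class[b]:
                raise ValueError(
                    f"planted edge ({a!r}, {b!r}) is within class "
                    f"{term_class[a]!r}; only cross-class edges are allowed")
        if not 0.0 <= self.assoc_doc_fraction <= 1.0:
            raise ValueError("assoc_doc_fraction must be in [0, 1]")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be positive")
        if self.n_docs < 0:
            raise ValueError("n_docs must be non-negative")
        if self.cooccur_gap < 1:
            raise ValueError("cooccur_gap must be >= 1")
        rates = [r for _, r in self.countries]
        if self.countries and not np.isclose(sum(rates), 1.0):
            raise ValueError("country mention rates must sum to 1")
        for code, _ in self.countries:
            if code not in CODE_TO_NAME:
                raise ValueError(f"no country name known for code {code!r}")

    @property
    def cross_class_terms(self) -> tuple[str, ...]:
        return self.disease_terms + self.food_terms + self.microbe_terms

    @classmethod
    def default(cls, n_docs: int = 2000, seed: int = 1,
                n_diseases: int = 20, n_microbes: int = 20,
                n_foods: int = 10, n_planted: int = 30,
                **overrides) -> "PlantedModel":
        """The standard study condition: 20 diseases x 20 microbes with 30
        planted disease-microbe edges, 30% association documents, plus a
        40-author pool over the default country distribution."""
        rng = np.random.default_rng(seed)
        diseases = tuple(f"malady{i:02d}" for i in range(n_diseases))
        microbes = tuple(f"bacterium{i:02d}" for i in range(n_microbes))
        foods = tuple(f"fooditem{i:02d}" for i in range(n_foods))
        pairs = [(d, m) for d in diseases for m in microbes]
        idx = rng.choice(len(pairs), size=min(n_planted, len(pairs)),
                         replace=False)
        planted = tuple(pairs[i] for i in sorted(idx))
        codes = [c for c, _ in DEFAULT_COUNTRY_RATES]
        rates = np.asarray([r for _, r in DEFAULT_COUNTRY_RATES])
        pool = []
        for i in range(40):
            k = 2 if rng.random() < 0.15 else 1
            affs = rng.choice(len(codes), size=k, replace=False, p=rates)
            pool.append((f"Author{i:02d}, Syn",
                         tuple(codes[j] for j in affs)))
        return cls(disease_terms=diseases, food_terms=foods,
                   microbe_terms=microbes, planted_edges=planted,
                   n_docs=n_docs, seed=seed, author_pool=tuple(pool),
                   **overrides)


@dataclass
class GroundTruth:
    """What the generator planted, derivable without sampling."""

    planted_edges: tuple[tuple[str, str], ...]
    expected_country_article_rates: dict[str, float]
    expected_author_tally: dict[str, int]


def _ground_truth(model: PlantedModel) -> GroundTruth:
    author_tally: dict[str, int] = {}
    for _, codes in model.author_pool:
        for code in set(codes):
            author_tally[code] = author_tally.get(code, 0) + 1
    return GroundTruth(
        planted_edges=model.planted_edges,
        expected_country_article_rates=dict(model.countries),
        expected_author_tally=author_tally)


def generate_corpus(model: PlantedModel) -> tuple[Corpus, GroundTruth]:
    """Sample a corpus from a :class:`PlantedModel`; fully seeded."""
    truth = _ground_truth(model)
    rng = np.random.default_rng(model.seed)
    V = model.background_vocab_size
    background = [f"w{k:04d}" for k in range(V)]
    p = 1.0 / np.arange(1, V + 1) ** model.zipf_exponent
    p /= p.sum()
    codes = [c for c, _ in model.countries]
    rates = np.asarray([r for _, r in model.countries])
    cross_terms = model.cross_class_terms
    base = _dt.date(2001, 1, 1)

    records: list[ArticleRecord] = []
    for i in range(model.n_docs):
        length = max(10, int(rng.poisson(model.doc_length)))
        tokens = [background[j]
                  for j in rng.choice(V, size=length, p=p)]
        if model.planted_edges and rng.random() < model.assoc_doc_fraction:
            a, b = model.planted_edges[int(rng.integers(len(model.planted_edges)))]
            gap = int(rng.integers(1, model.cooccur_gap + 1))
            pos = int(rng.integers(0, max(1, len(tokens) - gap + 1)))
            tokens.insert(pos, a)
            tokens.insert(pos + gap, b)
        if cross_terms and rng.random() < model.stray_term_prob:
            stray = cross_terms[int(rng.integers(len(cross_terms)))]
            tokens.insert(int(rng.integers(0, len(tokens) + 1)), stray)
        abstract = " ".join(tokens)
        if codes:
            code = codes[int(rng.choice(len(codes), p=rates))]
            abstract += f". This study was conducted in {CODE_TO_NAME[code]}."
        authors: list[AuthorRecord] = []
        if model.author_pool:
            n_auth = int(rng.integers(1, 5))
            picks = rng.choice(len(model.author_pool),
                               size=min(n_auth, len(model.author_pool)),
                               replace=False)
            for j in sorted(picks):
                name, ccodes = model.author_pool[j]
                affs = tuple(
                    f"Institute of Microbiome Science, {CODE_TO_NAME[c]}"
                    for c in ccodes)
                authors.append(AuthorRecord(display_name=name,
                                            affiliations=affs))
        records.append(ArticleRecord(
            pmid=f"SYN{i:07d}",
            title=f"Synthetic microbiome study {i:07d}",
            abstract=abstract,
            pub_date=base + _dt.timedelta(days=int(rng.integers(0, 7700))),
            authors=tuple(authors)))
    corpus = Corpus(records=records,
                    provenance={"generator": "microlit.synthetic",
                                "seed": model.seed, "n_docs": model.n_docs})
    return corpus, truth


# ---------------------------------------------------------------------------
# hand-built 10-document fixture suite
# ---------------------------------------------------------------------------

_FIXTURE_DOCS: tuple[tuple[str, str, str, str, tuple], ...] = (
    ("1001", "2018-05-01", "Gut microbiome and colorectal cancer",
     "We profiled fusobacterium nucleatum in colorectal cancer patients "
     "recruited in Japan. CRC incidence correlated with gut dysbiosis.",
     (("Tanaka, Hiro", ("University of Tokyo, Tokyo, Japan",)),)),
    ("1002", "2019-03-15", "Buckwheat diet and lactobacillus",
     "A buckwheat rich diet in Japan increased lactobacillus abundance.",
     (("Tanaka, Hiro", ("University of Tokyo, Tokyo, Japan",)),)),
    ("1003", "2020-07-20", "Dysentery surveillance",
     "Cases of dysentery linked to brachyspira hyodysenteriae in swine "
     "herds across Japan.",
     (("Tanaka, Hiro", ("University of Tokyo, Tokyo, Japan",)),)),
    ("1004", "2021-02-10", "Cross-national cohort",
     "A joint cohort between Japan and the United States examined rye "
     "bread intake and bifidobacterium abundance.",
     (("Smith, Jane", ("Harvard University, Boston, USA",
                       "RIKEN Center, Yokohama, Japan")),)),
    ("1005", "2021-11-05", "Celery fiber trial",
     "Celery fiber supplementation in the United States altered gut flora.",
     (("Garcia, Maria", ("University of Sao Paulo, Brazil",)),)),
    ("1006", "2017-01-30", "Remote sampling",
     "Soil microbiota sampling expeditions in Malawi and Antarctica. "
     "Children in Malawi were enrolled for stool collection.",
     (("Phiri, John", ("College of Medicine, Blantyre, Malawi",)),)),
    ("1007", "2016-09-09", "Urban microbiomes",
     "Built-environment samples from Boston and Shanghai were compared.",
     (("Chen, Wei", ("Fudan University, Shanghai, China",)),)),
    ("1008", "2015-04-22", "Methods note",
     "A turkey sandwich control diet was used; no geographic cohort was "
     "defined.",
     (("Doe, Alex", ("Institute of Advanced Studies",)),)),
    ("1009", "2022-01-12", "Amazon basin flora",
     "River communities in Brazil showed distinct verrucomicrobia "
     "signatures.",
     (("Garcia, Maria", ("University of Sao Paulo, Brazil",)),)),
    ("1010", "2014-06-18", "Dietary survey",
     "Sweetener consumption across India correlated with bacteroides "
     "fragilis carriage.",
     (("Kumar, Anil", ("AIIMS, New Delhi, India",)),)),
)

_FIXTURE_DICT_ROWS = (
    ("disease", "colorectal cancer", "colorectal cancer"),
    ("disease", "colorectal cancer", "CRC"),
    ("disease", "dysentery", "dysentery"),
    ("microbe", "fusobacterium nucleatum", "fusobacterium nucleatum"),
    ("microbe", "lactobacillus", "lactobacillus"),
    ("microbe", "brachyspira hyodysenteriae", "brachyspira hyodysenteriae"),
    ("microbe", "bifidobacterium", "bifidobacterium"),
    ("microbe", "verrucomicrobia", "verrucomicrobia"),
    ("microbe", "bacteroides fragilis", "bacteroides fragilis"),
    ("food", "buckwheat", "buckwheat"),
    ("food", "rye bread", "rye bread"),
    ("food", "celery", "celery"),
    ("food", "sweetener", "sweetener"),
    ("food", "turkey sandwich", "turkey sandwich"),
)

_FIXTURE_REFERENCE_ROWS = (
    ("fusobacterium nucleatum", "colorectal cancer"),
    ("bacteroides fragilis", "colorectal cancer"),
    ("brachyspira hyodysenteriae", "dysentery"),
    ("lactobacillus", "dysentery"),
    ("ghostbug mirabilis", "colorectal cancer"),  # deliberately unmappable
)


def fixture_corpus() -> Corpus:
    """The deterministic 10-document fixture corpus, built in memory."""
    records = []
    for pmid, date_s, title, abstract, authors in _FIXTURE_DOCS:
        records.append(ArticleRecord(
            pmid=pmid, title=title, abstract=abstract,
            pub_date=_dt.date.fromisoformat(date_s),
            authors=tuple(AuthorRecord(display_name=n, affiliations=tuple(a))
                          for n, a in authors)))
    return Corpus(records=records,
                  provenance={"generator": "microlit.synthetic.fixture"})


def emit_fixture_suite(out_dir: str | Path) -> dict[str, str]:
    """Write the unit-test fixture suite; returns {filename: sha256}.

    Files: the 10-document corpus (TSV and PubMed XML), the concept
    dictionaries, the default gazetteer and country metadata, a toy
    reference edge set, and a JSON manifest. Deterministic: two runs
    produce identical bytes.
    """
    from importlib import resources

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    corpus = fixture_corpus()
    write_corpus_tsv(corpus, out / "corpus.tsv")
    write_pubmed_xml(corpus, out / "corpus.xml")
    (out / "dictionaries.tsv").write_text(
        "".join(f"{c}\t{t}\t{s}\n" for c, t, s in _FIXTURE_DICT_ROWS),
        encoding="utf-8")
    data = resources.files("microlit") / "data"
    (out / "gazetteer.tsv").write_text(
        (data / "gazetteer.tsv").read_text(encoding="utf-8"), encoding="utf-8")
    (out / "country_meta.tsv").write_text(
        (data / "country_meta.tsv").read_text(encoding="utf-8"),
        encoding="utf-8")
    (out / "reference.tsv").write_text(
        "".join(f"{m}\t{d}\n" for m, d in _FIXTURE_REFERENCE_ROWS),
        encoding="utf-8")
    manifest = {}
    for name in sorted(p.name for p in out.iterdir()
                       if p.name != "manifest.json"):
        manifest[name] = hashlib.sha256(
            (out / name).read_bytes()).hexdigest()
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n",
        encoding="utf-8")
    return manifest
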