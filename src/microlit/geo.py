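"""Geo-bibliometrics: country assignment from text mentions and affiliations.

Two parallel tracks mirror two different questions about a literature:

* *article mentions* — a place name in the title or abstract is taken as a
  proxy for where the study was focused; each article votes at most once
  per country regardless of repeat mentions.
* *unique authors* — an author's affiliation countries are a proxy for where
  research activity (and funding) sits; each unique author, identified by
  their normalized name across the whole corpus, contributes exactly once
  to every country appearing in any of their affiliations.

Counts roll up to continents and to World Bank income classes, which are
loaded from a versioned TSV rather than hardcoded (the classification is
revised annually).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from .corpus import Corpus, TokenizedDocument, normalize_name

logger = logging.getLogger(__name__)

INCOME_CLASSES = ("High income", "Upper middle income",
                  "Lower middle income", "Low income", "Not classified")

UNKNOWN_CONTINENT = "Unknown continent"
NOT_CLASSIFIED = "Not classified"

TallyKind = Literal["article_mentions", "unique_authors"]


def _build_pattern(surfaces: Iterable[str]) -> re.Pattern | None:
    forms = sorted(set(surfaces), key=lambda s: (-len(s), s))
    if not forms:
        return None
    return re.compile(r"(?<!\w)(?:" + "|".join(re.escape(f) for f in forms)
                      + r")(?!\w)")


@dataclass
class Gazetteer:
    """Place-name surface forms mapped to ISO 3166-1 alpha-3 country codes.

    Most surface forms match case-insensitively; homographs of common words
    (e.g. "Turkey") are stored case-sensitively so that lowercase text
    occurrences do not produce spurious country hits.
    """

    ci_surfaces: dict[str, str] = field(default_factory=dict)  # lowercased
    cs_surfaces: dict[str, str] = field(default_factory=dict)  # verbatim
    country_to_continent: dict[str, str] = field(default_factory=dict)
    country_to_income: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for code in self.country_to_continent:
            self.country_to_income.setdefault(code, NOT_CLASSIFIED)
        self._ci_pattern = _build_pattern(self.ci_surfaces)
        self._cs_pattern = _build_pattern(self.cs_surfaces)

    # -- loading ------------------------------------------------------------

    @classmethod
    def from_tsv(cls, surfaces_path: str | Path,
                 meta_path: str | Path | None = None) -> "Gazetteer":
        """Load from ``surface<TAB>alpha3<TAB>ci|cs`` plus an optional
        ``alpha3<TAB>continent<TAB>income`` metadata table."""
        ci: dict[str, str] = {}
        cs: dict[str, str] = {}
        for lineno, line in enumerate(
                Path(surfaces_path).read_text(encoding="utf-8").splitlines(),
                start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{surfaces_path}:{lineno}: expected 3 columns")
            surface, code, mode = (p.strip() for p in parts)
            if mode == "ci":
                ci[surface.casefold()] = code
            elif mode == "cs":
                cs[surface] = code
            else:
                raise ValueError(
                    f"{surfaces_path}:{lineno}: match mode must be ci or cs")
        continent: dict[str, str] = {}
        income: dict[str, str] = {}
        if meta_path is not None:
            for lineno, line in enumerate(
                    Path(meta_path).read_text(encoding="utf-8").splitlines(),
                    start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ValueError(f"{meta_path}:{lineno}: expected 3 columns")
                code, cont, inc = (p.strip() for p in parts)
                continent[code] = cont
                income[code] = inc
        return cls(ci_surfaces=ci, cs_surfaces=cs,
                   country_to_continent=continent, country_to_income=income)

    @classmethod
    def default(cls) -> "Gazetteer":
        """The gazetteer shipped with the package (countries, major cities,
        continent and World Bank income metadata)."""
        data = resources.files("microlit") / "data"
        return cls.from_tsv(str(data / "gazetteer.tsv"),
                            str(data / "country_meta.tsv"))

    # -- matching -----------------------------------------------------------

    def find_countries(self, text: str) -> set[str]:
        """All country codes whose surface forms occur in ``text``
        (word-boundary anchored, longest match first)."""
        hits: set[str] = set()
        if self._ci_pattern is not None:
            for m in self._ci_pattern.finditer(text.casefold()):
                hits.add(self.ci_surfaces[m.group(0)])
        if self._cs_pattern is not None:
            for m in self._cs_pattern.finditer(text):
                hits.add(self.cs_surfaces[m.group(0)])
        return hits

    def continent_of(self, code: str) -> str:
        return self.country_to_continent.get(code, UNKNOWN_CONTINENT)

    def income_of(self, code: str) -> str:
        return self.country_to_income.get(code, NOT_CLASSIFIED)


@dataclass
class CountryTally:
    """Per-country counts for one track (article mentions or unique authors)."""

    kind: TallyKind
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("tally counts must be non-negative")

    def total(self) -> int:
        return sum(self.counts.values())

    def top(self, n: int = 20) -> list[tuple[str, int]]:
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))[:n]


def extract_country_mentions(doc: TokenizedDocument | str,
                             gaz: Gazetteer) -> set[str]:
    """Country codes mentioned in an article's title + abstract text.

    Repeat mentions of the same country count once; city hits map to their
    country.
    """
    text = doc if isinstance(doc, str) else doc.source_text
    return gaz.find_countries(text)


def map_affiliation_to_countries(affiliation: str, gaz: Gazetteer) -> set[str]:
    """Country codes found in a raw affiliation string (may be empty)."""
    codes = gaz.find_countries(affiliation)
    if not codes and affiliation.strip():
        logger.debug("no country found in affiliation: %r", affiliation)
    return codes


def tally_articles_by_country(corpus: Corpus, gaz: Gazetteer) -> CountryTally:
    """Number of articles mentioning each country (once per article)."""
    counts: dict[str, int] = {}
    for rec in corpus:
        for code in gaz.find_countries(rec.text):
            counts[code] = counts.get(code, 0) + 1
    return CountryTally(kind="article_mentions", counts=counts)


def tally_authors_by_country(corpus: Corpus, gaz: Gazetteer) -> CountryTally:
    """Number of unique authors affiliated with each country.

    Author identity is the normalized name string; an author publishing many
    papers counts once, and an author with affiliations in several countries
    counts once for each of those countries.
    """
    author_countries: dict[str, set[str]] = {}
    for rec in corpus:
        for author in rec.authors:
            key = author.normalized_name
            bucket = author_countries.setdefault(key, set())
            for aff in author.affiliations:
                bucket |= map_affiliation_to_countries(aff, gaz)
    counts: dict[str, int] = {}
    for codes in author_countries.values():
        for code in codes:
            counts[code] = counts.get(code, 0) + 1
    return CountryTally(kind="unique_authors", counts=counts)


def aggregate(tally: CountryTally, level: Literal["continent", "income"],
              gaz: Gazetteer) -> dict[str, int]:
    """Group-sum a country tally by continent or income class.

    Countries absent from the gazetteer metadata are routed to
    "Unknown continent" / "Not classified" with a warning; totals are
    conserved.
    """
    if level == "continent":
        keyfn = gaz.continent_of
        fallback = UNKNOWN_CONTINENT
        known = gaz.country_to_continent
    elif level == "income":
        keyfn = gaz.income_of
        fallback = NOT_CLASSIFIED
        known = gaz.country_to_income
    else:
        raise ValueError(f"level must be 'continent' or 'income', got {level!r}")
    out: dict[str, int] = {}
    for code, n in tally.counts.items():
        if code not in known:
            logger.warning("country %s missing from %s map; counted as %r",
                           code, level, fallback)
        group = keyfn(code)
        out[group] = out.get(group, 0) + n
    return out


def scatter_table(articles: CountryTally, authors: CountryTally,
                  gaz: Gazetteer) -> pd.DataFrame:
    """Per-country article vs author counts with log10 fields and income class.

    The row set is the union of countries in either tally; a zero count is
    emitted as 0 with its log10 field left as NaN (undefined).
    """
    codes = sorted(set(articles.counts) | set(authors.counts))
    rows = []
    for code in codes:
        a = articles.counts.get(code, 0)
        b = authors.counts.get(code, 0)
        rows.append({
            "country": code,
            "article_count": a,
            "author_count": b,
            "log10_articles": np.log10(a) if a > 0 else np.nan,
            "log10_authors": np.log10(b) if b > 0 else np.nan,
            "income_class": gaz.income_of(code),
        })
    return pd.DataFrame(
        rows, columns=["country", "article_count", "author_count",
                       "log10_articles", "log10_authors", "income_class"])
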