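"""Corpus ingestion: PubMed-format abstract records, filtering and tokenization.

Records are read either from PubMed XML (``PubmedArticleSet``) or from a simple
5-column TSV dialect used for fixtures and normalized dumps::

    pmid <TAB> date(ISO-8601 or empty) <TAB> title <TAB> abstract <TAB> authors

where the authors column holds ``name|aff1;aff2`` groups joined by `` // ``.
"""

from __future__ import annotations

import datetime as _dt
import logging
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from lxml import etree

logger = logging.getLogger(__name__)

_AUTHOR_GROUP_SEP = " // "

# Lowercase alphanumeric runs, keeping internal hyphens and underscores
# (underscores carry fused multiword concept terms). No stemming, no
# stopword removal: the embedding window statistics do the work downstream.
_TOKEN_RE = re.compile(r"[0-9a-z]+(?:[-_][0-9a-z]+)*")

_MONTHS = {m: i for i, m in enumerate(
    ["jan", "feb", "mar", "apr", "may", "jun",
     "jul", "aug", "sep", "oct", "nov", "dec"], start=1)}


def normalize_name(name: str) -> str:
    """Case-fold, collapse whitespace and strip diacritics from a person name."""
    decomposed = unicodedata.normalize("NFKD", name)
    stripped = "".join(c for c in decomposed if not unicodedata.combining(c))
    return " ".join(stripped.casefold().split())


@dataclass(frozen=True)
class AuthorRecord:
    """One author of one article: display name plus raw affiliation strings."""

    display_name: str
    affiliations: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        norm = normalize_name(self.display_name)
        if not norm:
            raise ValueError("author display_name empty after normalization")

    @property
    def normalized_name(self) -> str:
        return normalize_name(self.display_name)


@dataclass(frozen=True)
class ArticleRecord:
    """One publication: identifier, title, abstract, date and author list.

    ``pub_date`` is ``None`` when the source record carried no parseable
    date; it is never silently defaulted.
    """

    pmid: str
    title: str
    abstract: str = ""
    pub_date: _dt.date | None = None
    authors: tuple[AuthorRecord, ...] = ()

    def __post_init__(self) -> None:
        if not self.pmid:
            raise ValueError("pmid must be non-empty")

    @property
    def text(self) -> str:
        """Title and abstract joined on a sentence boundary."""
        if self.abstract:
            return f"{self.title} {self.abstract}" if self.title else self.abstract
        return self.title


@dataclass
class Corpus:
    """An ordered, pmid-unique collection of :class:`ArticleRecord`."""

    records: list[ArticleRecord] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.pmid in seen:
                raise ValueError(f"duplicate pmid in Corpus: {rec.pmid}")
            seen.add(rec.pmid)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ArticleRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> ArticleRecord:
        return self.records[i]


@dataclass(frozen=True)
class TokenizedDocument:
    """Lowercase token stream for one article (title + abstract)."""

    pmid: str
    tokens: tuple[str, ...]
    source_text: str = ""


def tokenize(text: str) -> list[str]:
    """Lowercase and split on punctuation/whitespace, keeping internal hyphens.

    Digits are retained; there is no stopword removal.

    >>> tokenize("16S rRNA-based survey.")
    ['16s', 'rrna-based', 'survey']
    """
    return _TOKEN_RE.findall(text.casefold())


def preprocess(record: ArticleRecord) -> TokenizedDocument:
    """Tokenize an article's title + abstract into a :class:`TokenizedDocument`."""
    text = record.text
    return TokenizedDocument(pmid=record.pmid, tokens=tuple(tokenize(text)),
                             source_text=text)


def preprocess_corpus(corpus: Corpus) -> list[TokenizedDocument]:
    return [preprocess(rec) for rec in corpus]


# ---------------------------------------------------------------------------
# PubMed XML
# ---------------------------------------------------------------------------

def _parse_pubdate(article: etree._Element) -> _dt.date | None:
    node = article.find(".//Article/Journal/JournalIssue/PubDate")
    if node is None:
        node = article.find(".//PubDate")
    if node is None:
        return None
    year = node.findtext("Year")
    if year is None:
        medline = node.findtext("MedlineDate")
        if medline:
            m = re.search(r"(\d{4})", medline)
            if m:
                return _dt.date(int(m.group(1)), 1, 1)
        return None
    month_txt = (node.findtext("Month") or "1").strip().casefold()
    month = _MONTHS.get(month_txt[:3], None)
    if month is None:
        try:
            month = int(month_txt)
        except ValueError:
            month = 1
    try:
        day = int(node.findtext("Day") or 1)
    except ValueError:
        day = 1
    try:
        return _dt.date(int(year), month, day)
    except ValueError:
        return _dt.date(int(year), 1, 1)


def _parse_authors(article: etree._Element) -> tuple[AuthorRecord, ...]:
    out = []
    for author in article.findall(".//Article/AuthorList/Author"):
        last = author.findtext("LastName") or ""
        fore = author.findtext("ForeName") or author.findtext("Initials") or ""
        collective = author.findtext("CollectiveName") or ""
        name = f"{last}, {fore}".strip(", ") if (last or fore) else collective
        if not name.strip():
            continue
        affs = tuple(a.text.strip() for a in
                     author.findall("AffiliationInfo/Affiliation")
                     if a.text and a.text.strip())
        out.append(AuthorRecord(display_name=name, affiliations=affs))
    return tuple(out)


def parse_pubmed_xml(paths: Sequence[str | Path]) -> Corpus:
    """Parse one or more PubMed ``PubmedArticleSet`` XML files into a Corpus.

    One record per ``PubmedArticle``; entries without a PMID are rejected
    with a warning, and duplicate PMIDs across files keep the first
    occurrence. Records lacking an abstract are kept with an empty abstract.
    """
    records: list[ArticleRecord] = []
    seen: set[str] = set()
    for path in paths:
        path = Path(path)
        try:
            tree = etree.parse(str(path))
        except etree.XMLSyntaxError as exc:
            raise ValueError(f"malformed PubMed XML in {path}: {exc}") from exc
        for article in tree.getroot().iterfind(".//PubmedArticle"):
            pmid = article.findtext(".//MedlineCitation/PMID")
            if not pmid or not pmid.strip():
                logger.warning("record without PMID rejected in %s", path)
                continue
            pmid = pmid.strip()
            if pmid in seen:
                logger.warning("duplicate pmid %s ignored (kept first)", pmid)
                continue
            seen.add(pmid)
            title = "".join(
                (article.find(".//Article/ArticleTitle").itertext())
            ).strip() if article.find(".//Article/ArticleTitle") is not None else ""
            abstract_parts = [
                "".join(t.itertext()).strip()
                for t in article.findall(".//Article/Abstract/AbstractText")
            ]
            abstract = " ".join(p for p in abstract_parts if p)
            if not abstract:
                logger.info("pmid %s has no abstract; kept with empty text", pmid)
            records.append(ArticleRecord(
                pmid=pmid, title=title, abstract=abstract,
                pub_date=_parse_pubdate(article),
                authors=_parse_authors(article)))
    if not records:
        logger.warning("no records parsed from %d file(s): empty corpus",
                       len(paths))
    return Corpus(records=records,
                  provenance={"sources": [str(p) for p in paths],
                              "format": "pubmed-xml"})


def write_pubmed_xml(corpus: Corpus, path: str | Path) -> None:
    """Serialize a corpus as a minimal ``PubmedArticleSet`` document."""
    root = etree.Element("PubmedArticleSet")
    for rec in corpus:
        art = etree.SubElement(root, "PubmedArticle")
        cit = etree.SubElement(art, "MedlineCitation")
        etree.SubElement(cit, "PMID").text = rec.pmid
        article = etree.SubElement(cit, "Article")
        journal = etree.SubElement(article, "Journal")
        issue = etree.SubElement(journal, "JournalIssue")
        pubdate = etree.SubElement(issue, "PubDate")
        if rec.pub_date is not None:
            etree.SubElement(pubdate, "Year").text = str(rec.pub_date.year)
            etree.SubElement(pubdate, "Month").text = str(rec.pub_date.month)
            etree.SubElement(pubdate, "Day").text = str(rec.pub_date.day)
        etree.SubElement(article, "ArticleTitle").text = rec.title
        if rec.abstract:
            abstract = etree.SubElement(article, "Abstract")
            etree.SubElement(abstract, "AbstractText").text = rec.abstract
        if rec.authors:
            alist = etree.SubElement(article, "AuthorList")
            for a in rec.authors:
                author = etree.SubElement(alist, "Author")
                last, _, fore = a.display_name.partition(", ")
                etree.SubElement(author, "LastName").text = last
                if fore:
                    etree.SubElement(author, "ForeName").text = fore
                for aff in a.affiliations:
                    info = etree.SubElement(author, "AffiliationInfo")
                    etree.SubElement(info, "Affiliation").text = aff
    Path(path).write_bytes(etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"))


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

def _clean_cell(text: str) -> str:
    return text.replace("\t", " ").replace("\n", " ").replace("\r", " ")


def write_corpus_tsv(corpus: Corpus, path: str | Path) -> None:
    """Dump a corpus in the 5-column fixture TSV dialect."""
    lines = []
    for rec in corpus:
        groups = []
        for a in rec.authors:
            affs = ";".join(_clean_cell(x) for x in a.affiliations)
            groups.append(f"{_clean_cell(a.display_name)}|{affs}")
        lines.append("\t".join([
            rec.pmid,
            rec.pub_date.isoformat() if rec.pub_date else "",
            _clean_cell(rec.title),
            _clean_cell(rec.abstract),
            _AUTHOR_GROUP_SEP.join(groups),
        ]))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""),
                          encoding="utf-8")


def read_corpus_tsv(path: str | Path) -> Corpus:
    """Read the 5-column fixture TSV dialect back into a Corpus."""
    records: list[ArticleRecord] = []
    seen: set[str] = set()
    for lineno, line in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise ValueError(
                f"{path}:{lineno}: expected 5 tab-separated columns, "
                f"got {len(parts)}")
        pmid, date_s, title, abstract, authors_s = parts
        if pmid in seen:
            logger.warning("duplicate pmid %s ignored (kept first)", pmid)
            continue
        seen.add(pmid)
        authors = []
        if authors_s:
            for group in authors_s.split(_AUTHOR_GROUP_SEP):
                name, _, affs = group.partition("|")
                affiliations = tuple(a for a in affs.split(";") if a)
                if name.strip():
                    authors.append(AuthorRecord(display_name=name,
                                                affiliations=affiliations))
        records.append(ArticleRecord(
            pmid=pmid, title=title, abstract=abstract,
            pub_date=_dt.date.fromisoformat(date_s) if date_s else None,
            authors=tuple(authors)))
    return Corpus(records=records,
                  provenance={"sources": [str(path)], "format": "tsv"})


def load_corpus(path: str | Path) -> Corpus:
    """Load a corpus from PubMed XML or fixture TSV, sniffing by extension."""
    path = Path(path)
    if path.suffix.casefold() == ".xml":
        return parse_pubmed_xml([path])
    return read_corpus_tsv(path)


def filter_by_date(corpus: Corpus, start: _dt.date, end: _dt.date) -> Corpus:
    """Keep records with ``start <= pub_date <= end``; undated ones are dropped.

    Order is preserved; the number of excluded undated records is logged.
    """
    if start > end:
        raise ValueError(f"start {start} is after end {end}")
    kept, undated = [], 0
    for rec in corpus:
        if rec.pub_date is None:
            undated += 1
            continue
        if start <= rec.pub_date <= end:
            kept.append(rec)
    if undated:
        logger.info("filter_by_date dropped %d record(s) with missing dates",
                    undated)
    return Corpus(records=kept,
                  provenance={**corpus.provenance,
                              "date_filter": [start.isoformat(),
                                              end.isoformat()]})
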