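"""Dictionary-based concept tagging for disease, food and microbe terms.

Tagging is greedy left-to-right longest-match over the token stream,
case-insensitive, with matched tokens consumed so spans never overlap.
On equal-length cross-class ties the default precedence is
microbe > disease > food (species binomials are the most specific
nomenclature); the order is configurable.

Multiword matches are then fused into single underscore-joined tokens
(``fusobacterium nucleatum`` -> ``fusobacterium_nucleatum``) and synonyms
are canonicalized, so the embedding stage learns exactly one phrase vector
per canonical term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .corpus import TokenizedDocument, tokenize

logger = logging.getLogger(__name__)

CONCEPT_CLASSES = ("disease", "food", "microbe")
DEFAULT_PRECEDENCE = ("microbe", "disease", "food")


def fused_token(term: str) -> str:
    """Canonical single-token form of a (possibly multiword) term."""
    return "_".join(tokenize(term))


@dataclass
class TermDictionary:
    """Vocabulary of one concept class: canonical term -> surface forms.

    Surface forms are stored as tuples of tokens produced by the corpus
    tokenizer, so matching is representation-consistent with the documents.
    """

    concept_class: str
    entries: dict[str, set[tuple[str, ...]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for canonical, surfaces in self.entries.items():
            for s in surfaces:
                if not s:
                    raise ValueError(
                        f"empty surface form for {canonical!r} "
                        f"({self.concept_class})")

    def add(self, canonical: str, surface: str) -> None:
        toks = tuple(tokenize(surface))
        if not toks:
            raise ValueError(f"surface {surface!r} tokenizes to nothing")
        self.entries.setdefault(canonical, set()).add(toks)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def canonical_terms(self) -> list[str]:
        return sorted(self.entries)


@dataclass(frozen=True)
class TaggedSpan:
    """One accepted dictionary match: [token_start, token_end) in a document."""

    pmid: str
    token_start: int
    token_end: int
    concept_class: str
    canonical_term: str

    def __post_init__(self) -> None:
        if not self.token_start < self.token_end:
            raise ValueError("span must satisfy token_start < token_end")

    def __len__(self) -> int:
        return self.token_end - self.token_start


def load_dictionaries(paths: Sequence[str | Path]) -> list[TermDictionary]:
    """Load ``class<TAB>canonical<TAB>surface`` TSV files (one surface/row).

    A surface form assigned to two different classes is a hard load error:
    the downstream tie rules assume every surface belongs to one class.
    """
    dicts: dict[str, TermDictionary] = {}
    surface_owner: dict[tuple[str, ...], str] = {}
    for path in paths:
        for lineno, line in enumerate(
                Path(path).read_text(encoding="utf-8").splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            cls, canonical, surface = (p.strip() for p in parts)
            if cls not in CONCEPT_CLASSES:
                raise ValueError(
                    f"{path}:{lineno}: unknown concept class {cls!r}")
            toks = tuple(tokenize(surface))
            if not toks:
                raise ValueError(
                    f"{path}:{lineno}: surface {surface!r} tokenizes to nothing")
            owner = surface_owner.get(toks)
            if owner is not None and owner != cls:
                raise ValueError(
                    f"{path}:{lineno}: surface {surface!r} assigned to both "
                    f"{owner!r} and {cls!r}")
            surface_owner[toks] = cls
            dicts.setdefault(cls, TermDictionary(concept_class=cls)) \
                 .add(canonical, surface)
    return [dicts[c] for c in CONCEPT_CLASSES if c in dicts]


class _Matcher:
    """First-token index over all dictionaries for greedy longest-match."""

    def __init__(self, dicts: Iterable[TermDictionary],
                 precedence: Sequence[str] = DEFAULT_PRECEDENCE):
        rank = {c: i for i, c in enumerate(precedence)}
        self.index: dict[str, list[tuple[tuple[str, ...], str, str]]] = {}
        for d in dicts:
            for canonical, surfaces in d.entries.items():
                for toks in surfaces:
                    self.index.setdefault(toks[0], []).append(
                        (toks, d.concept_class, canonical))
        for cands in self.index.values():
            # longest first; ties broken by class precedence, then term name
            cands.sort(key=lambda t: (-len(t[0]),
                                      rank.get(t[1], len(rank)), t[2]))

    def match_at(self, tokens: Sequence[str], i: int):
        for toks, cls, canonical in self.index.get(tokens[i], ()):
            if tuple(tokens[i:i + len(toks)]) == toks:
                return toks, cls, canonical
        return None


def tag_document(doc: TokenizedDocument, dicts: Sequence[TermDictionary],
                 precedence: Sequence[str] = DEFAULT_PRECEDENCE
                 ) -> list[TaggedSpan]:
    """Greedy left-to-right longest-match tagging of one document."""
    matcher = dicts if isinstance(dicts, _Matcher) else _Matcher(dicts, precedence)
    spans: list[TaggedSpan] = []
    tokens = doc.tokens
    i = 0
    while i < len(tokens):
        hit = matcher.match_at(tokens, i)
        if hit is None:
            i += 1
            continue
        toks, cls, canonical = hit
        spans.append(TaggedSpan(pmid=doc.pmid, token_start=i,
                                token_end=i + len(toks),
                                concept_class=cls, canonical_term=canonical))
        i += len(toks)
    return spans


def tag_corpus(docs: Sequence[TokenizedDocument],
               dicts: Sequence[TermDictionary],
               precedence: Sequence[str] = DEFAULT_PRECEDENCE
               ) -> dict[str, list[TaggedSpan]]:
    matcher = _Matcher(dicts, precedence)
    return {doc.pmid: tag_document(doc, matcher) for doc in docs}


def fuse_phrases(doc: TokenizedDocument,
                 spans: Sequence[TaggedSpan]) -> TokenizedDocument:
    """Rewrite tagged spans as single canonical tokens.

    Each span's tokens are replaced by the underscore-joined canonical term,
    so synonyms collapse onto one vocabulary item and the token count
    decreases by the sum of (span length - 1).
    """
    ordered = sorted(spans, key=lambda s: s.token_start)
    for a, b in zip(ordered, ordered[1:]):
        if b.token_start < a.token_end:
            raise RuntimeError(
                f"overlapping spans at tokens {a.token_start}..{b.token_end} "
                f"in {doc.pmid}: tag_document contract violated")
    out: list[str] = []
    i = 0
    for span in ordered:
        out.extend(doc.tokens[i:span.token_start])
        out.append(fused_token(span.canonical_term))
        i = span.token_end
    out.extend(doc.tokens[i:])
    return TokenizedDocument(pmid=doc.pmid, tokens=tuple(out),
                             source_text=doc.source_text)


def fuse_corpus(docs: Sequence[TokenizedDocument],
                dicts: Sequence[TermDictionary],
                precedence: Sequence[str] = DEFAULT_PRECEDENCE
                ) -> list[TokenizedDocument]:
    """Tag and fuse every document; the standard pre-embedding step."""
    matcher = _Matcher(dicts, precedence)
    return [fuse_phrases(doc, tag_document(doc, matcher)) for doc in docs]


# -- TaggedSpan TSV interchange (bypass for external NER output) ------------

def write_spans_tsv(spans: Iterable[TaggedSpan], path: str | Path) -> None:
    lines = [f"{s.pmid}\t{s.token_start}\t{s.token_end}\t"
             f"{s.concept_class}\t{s.canonical_term}" for s in spans]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""),
                          encoding="utf-8")


def read_spans_tsv(path: str | Path) -> list[TaggedSpan]:
    spans = []
    for lineno, line in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise ValueError(f"{path}:{lineno}: expected 5 columns")
        pmid, start, end, cls, canonical = parts
        spans.append(TaggedSpan(pmid=pmid, token_start=int(start),
                                token_end=int(end), concept_class=cls,
                                canonical_term=canonical))
    return spans
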