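"""Cosine-threshold semantic networks between concept classes.

A semantic network at threshold ``theta`` is the bipartite graph whose
nodes are concept terms (from two classes, e.g. disease and microbe) that
have embedding vectors, and whose edges join cross-class term pairs with
cosine distance at most ``theta``. Low-theta networks keep only the most
confident associations; raising theta admits more nodes and edges.

The module also provides threshold sweeps (one all-pairs distance pass,
binned), nearest-neighbour queries around a focus term, dense distance
heatmaps, coverage validation against a curated reference edge set, and
GraphML / TSV export.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .embedding import EmbeddingModel
from .tagging import fused_token

logger = logging.getLogger(__name__)

CLASS_PAIRS = (("disease", "microbe"), ("disease", "food"),
               ("microbe", "food"))

#: default sweep grid 0.00..1.00 step 0.05 (distances > 1 mean
#: anti-correlated vectors and are rarely meaningful)
DEFAULT_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 2))

_HIST_BINS = np.round(np.arange(0.0, 2.0001, 0.05), 2)


def _normalize_pair(class_pair) -> tuple[str, str]:
    if isinstance(class_pair, str):
        parts = class_pair.replace("_", "-").split("-")
        if len(parts) != 2:
            raise ValueError(f"cannot parse class pair {class_pair!r}")
        class_pair = tuple(parts)
    a, b = class_pair
    if a == b:
        raise ValueError("class pair must join two distinct classes")
    for known in CLASS_PAIRS:
        if set(known) == {a, b}:
            return known
    raise ValueError(
        f"unknown class pair {a!r}-{b!r}; expected one of "
        + ", ".join("-".join(p) for p in CLASS_PAIRS))


def _present_terms(model: EmbeddingModel, terms: Sequence[str]) -> list[str]:
    present, dropped = [], []
    for t in terms:
        (present if model.term_vector(t) is not None else dropped).append(t)
    if dropped:
        logger.info("%d term(s) without vectors skipped: %s",
                    len(dropped), ", ".join(sorted(dropped)[:5]))
    return present


def _distance_matrix(model: EmbeddingModel, terms_a: Sequence[str],
                     terms_b: Sequence[str]) -> np.ndarray:
    """Dense cosine-distance matrix between two present-term lists."""
    A = np.asarray([model.term_vector(t) for t in terms_a], dtype=np.float64)
    B = np.asarray([model.term_vector(t) for t in terms_b], dtype=np.float64)
    A /= np.linalg.norm(A, axis=1, keepdims=True)
    B /= np.linalg.norm(B, axis=1, keepdims=True)
    return 1.0 - np.clip(A @ B.T, -1.0, 1.0)


@dataclass
class SemanticNetwork:
    """Bipartite cosine-threshold graph between two concept classes."""

    theta: float
    class_pair: tuple[str, str]
    graph: nx.Graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> list[tuple[str, str, float]]:
        return [(u, v, d["cosine_distance"])
                for u, v, d in self.graph.edges(data=True)]


def build_network(model: EmbeddingModel,
                  terms_by_class: Mapping[str, Sequence[str]],
                  class_pair, theta: float,
                  keep_isolated: bool = False,
                  use_similarity: bool = False) -> SemanticNetwork:
    """Exhaustive cross-class pair enumeration; edge iff distance <= theta.

    Terms without vectors are skipped (logged). By default nodes with no
    edge at this theta are excluded, so node counts grow with the
    threshold; ``keep_isolated=True`` retains the full vector-backed term
    sets as nodes. ``use_similarity=True`` reads theta as a *similarity*
    floor (edge iff similarity >= theta) instead of a distance ceiling.
    """
    cls_a, cls_b = _normalize_pair(class_pair)
    if not (0.0 <= theta <= 2.0) and not use_similarity:
        raise ValueError(f"theta must be in [0, 2], got {theta}")
    terms_a = _present_terms(model, terms_by_class[cls_a])
    terms_b = _present_terms(model, terms_by_class[cls_b])
    g = nx.Graph()
    if keep_isolated:
        for t in terms_a:
            g.add_node(t, concept_class=cls_a)
        for t in terms_b:
            g.add_node(t, concept_class=cls_b)
    if terms_a and terms_b:
        D = _distance_matrix(model, terms_a, terms_b)
        mask = (1.0 - D >= theta) if use_similarity else (D <= theta)
        for i, j in zip(*np.nonzero(mask)):
            g.add_node(terms_a[i], concept_class=cls_a)
            g.add_node(terms_b[j], concept_class=cls_b)
            g.add_edge(terms_a[i], terms_b[j], cosine_distance=float(D[i, j]))
    return SemanticNetwork(theta=theta, class_pair=(cls_a, cls_b), graph=g)


@dataclass
class ThresholdSweep:
    """Node/edge counts of the network family over an ascending theta grid."""

    class_pair: tuple[str, str]
    grid: tuple[float, ...]
    edge_counts: tuple[int, ...]
    node_counts: tuple[int, ...]
    node_counts_by_class: dict[str, tuple[int, ...]]
    histogram_bin_edges: tuple[float, ...]
    histogram_counts: tuple[int, ...]

    def to_frame(self) -> pd.DataFrame:
        cls_a, cls_b = self.class_pair
        return pd.DataFrame({
            "theta": self.grid,
            "n_edges": self.edge_counts,
            "n_nodes": self.node_counts,
            f"n_nodes_{cls_a}": self.node_counts_by_class[cls_a],
            f"n_nodes_{cls_b}": self.node_counts_by_class[cls_b],
        })


def sweep_thresholds(model: EmbeddingModel,
                     terms_by_class: Mapping[str, Sequence[str]],
                     class_pair,
                     grid: Sequence[float] = DEFAULT_GRID) -> ThresholdSweep:
    """Counts at every grid point from a single all-pairs distance pass."""
    grid = tuple(float(t) for t in grid)
    if any(b < a for a, b in zip(grid, grid[1:])):
        raise ValueError("threshold grid must be ascending")
    if grid and not (0.0 <= grid[0] and grid[-1] <= 2.0):
        raise ValueError("threshold grid must lie within [0, 2]")
    cls_a, cls_b = _normalize_pair(class_pair)
    terms_a = _present_terms(model, terms_by_class[cls_a])
    terms_b = _present_terms(model, terms_by_class[cls_b])
    if terms_a and terms_b:
        D = _distance_matrix(model, terms_a, terms_b)
    else:
        D = np.empty((len(terms_a), len(terms_b)))
    edge_counts, node_counts, nodes_a, nodes_b = [], [], [], []
    for theta in grid:
        mask = D <= theta
        na = int(mask.any(axis=1).sum())
        nb = int(mask.any(axis=0).sum())
        edge_counts.append(int(mask.sum()))
        nodes_a.append(na)
        nodes_b.append(nb)
        node_counts.append(na + nb)
    hist, _ = np.histogram(D.ravel(), bins=_HIST_BINS)
    return ThresholdSweep(
        class_pair=(cls_a, cls_b), grid=grid,
        edge_counts=tuple(edge_counts), node_counts=tuple(node_counts),
        node_counts_by_class={cls_a: tuple(nodes_a), cls_b: tuple(nodes_b)},
        histogram_bin_edges=tuple(float(x) for x in _HIST_BINS),
        histogram_counts=tuple(int(x) for x in hist))


def neighborhood(model: EmbeddingModel, focus_term: str,
                 partner_terms: Sequence[str], k: int = 10,
                 theta: float | None = None) -> list[tuple[str, float]]:
    """Partner-class terms ranked by ascending cosine distance to the focus.

    Ties are broken lexicographically for determinism; an optional theta
    filters the ranking before truncation to k.
    """
    fv = model.term_vector(focus_term)
    if fv is None:
        raise KeyError(f"focus term {focus_term!r} has no vector "
                       "(below min_count or absent from corpus)")
    present = _present_terms(model, [t for t in partner_terms
                                     if fused_token(t) != fused_token(focus_term)])
    if not present:
        return []
    D = _distance_matrix(model, [focus_term], present)[0]
    ranked = sorted(zip(present, D), key=lambda td: (td[1], td[0]))
    if theta is not None:
        ranked = [(t, d) for t, d in ranked if d <= theta]
    return [(t, float(d)) for t, d in ranked[:k]]


def heatmap_matrix(model: EmbeddingModel, terms_a: Sequence[str],
                   terms_b: Sequence[str]) -> pd.DataFrame:
    """Dense cosine-distance matrix (rows = terms_a, cols = terms_b).

    Terms without vectors are dropped with a log message.
    """
    rows = _present_terms(model, terms_a)
    cols = _present_terms(model, terms_b)
    if not rows or not cols:
        return pd.DataFrame(index=rows, columns=cols, dtype=float)
    return pd.DataFrame(_distance_matrix(model, rows, cols),
                        index=rows, columns=cols)


# ---------------------------------------------------------------------------
# reference-edge coverage
# ---------------------------------------------------------------------------

@dataclass
class ReferenceEdgeSet:
    """Curated cross-class term pairs (e.g. microbe-disease associations
    from a manually curated database) used to validate the network."""

    pairs: tuple[tuple[str, str], ...]
    class_pair: tuple[str, str] = ("microbe", "disease")
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("reference pairs must be unique")

    @classmethod
    def from_tsv(cls, path: str | Path,
                 class_pair=("microbe", "disease"),
                 provenance: str = "") -> "ReferenceEdgeSet":
        """Load ``classA_term<TAB>classB_term`` rows."""
        pairs = []
        for lineno, line in enumerate(
                Path(path).read_text(encoding="utf-8").splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            pairs.append((parts[0].strip(), parts[1].strip()))
        return cls(pairs=tuple(dict.fromkeys(pairs)),
                   class_pair=_normalize_pair(class_pair),
                   provenance=provenance or str(path))


@dataclass
class CoverageReport:
    """How much of a curated reference edge set the network recovers.

    A pair is *mappable* when both endpoints have vectors; unmappable pairs
    (a term never meeting min_count in the corpus) are counted separately —
    they explain misses without reflecting on the embedding itself.
    """

    n_reference: int
    n_mappable: int
    grid: tuple[float, ...]
    n_found_at: dict[float, int]
    coverage_fraction_at: dict[float, float]
    mappable_distances: tuple[float, ...]
    histogram_bin_edges: tuple[float, ...]
    histogram_counts: tuple[int, ...]

    @property
    def n_unmappable(self) -> int:
        return self.n_reference - self.n_mappable

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "theta": self.grid,
            "n_found": [self.n_found_at[t] for t in self.grid],
            "coverage_fraction": [self.coverage_fraction_at[t]
                                  for t in self.grid],
        })


def coverage_against_reference(model: EmbeddingModel, ref: ReferenceEdgeSet,
                               grid: Sequence[float] = DEFAULT_GRID,
                               synonym_map: Mapping[str, str] | None = None
                               ) -> CoverageReport:
    """Count reference pairs recovered as edges at each threshold.

    ``synonym_map`` translates external nomenclature to the corpus
    canonical terms before lookup. Coverage at theta is
    n_found / n_reference; distance bins cover mappable pairs only.
    """
    if not ref.pairs:
        raise ValueError("reference edge set is empty")
    grid = tuple(float(t) for t in grid)
    if any(b < a for a, b in zip(grid, grid[1:])):
        raise ValueError("threshold grid must be ascending")
    syn = synonym_map or {}
    distances = []
    for a, b in ref.pairs:
        va = model.term_vector(syn.get(a, a))
        vb = model.term_vector(syn.get(b, b))
        if va is None or vb is None:
            continue
        va = va / np.linalg.norm(va)
        vb = vb / np.linalg.norm(vb)
        distances.append(1.0 - float(np.clip(va @ vb, -1.0, 1.0)))
    dist_arr = np.asarray(distances)
    n_found = {t: int((dist_arr <= t).sum()) for t in grid}
    hist, _ = np.histogram(dist_arr, bins=_HIST_BINS)
    return CoverageReport(
        n_reference=len(ref.pairs), n_mappable=len(distances),
        grid=grid, n_found_at=n_found,
        coverage_fraction_at={t: n_found[t] / len(ref.pairs) for t in grid},
        mappable_distances=tuple(float(d) for d in sorted(distances)),
        histogram_bin_edges=tuple(float(x) for x in _HIST_BINS),
        histogram_counts=tuple(int(x) for x in hist))


# ---------------------------------------------------------------------------
# recovery scoring and export
# ---------------------------------------------------------------------------

def planted_recovery_auroc(model: EmbeddingModel,
                           planted_edges: Iterable[tuple[str, str]],
                           terms_a: Sequence[str],
                           terms_b: Sequence[str]) -> float:
    """AUROC of ascending-distance ranking: planted vs non-planted pairs.

    All cross-class pairs with vectors are ranked by cosine distance; an
    ideal embedding places every planted pair ahead of every non-planted
    one (AUROC 1.0; chance is 0.5).
    """
    from sklearn.metrics import roc_auc_score

    planted = {frozenset(p) for p in planted_edges}
    pa = _present_terms(model, terms_a)
    pb = _present_terms(model, terms_b)
    D = _distance_matrix(model, pa, pb)
    labels, scores = [], []
    for i, a in enumerate(pa):
        for j, b in enumerate(pb):
            labels.append(1 if frozenset((a, b)) in planted else 0)
            scores.append(-D[i, j])  # low distance should score high
    if len(set(labels)) < 2:
        raise ValueError("need both planted and non-planted pairs in vocab")
    return float(roc_auc_score(labels, scores))


def export_network(net: SemanticNetwork, path: str | Path,
                   format: str | None = None) -> Path:
    """Write GraphML (node attr ``concept_class``, edge attr
    ``cosine_distance``) or a 5-column edge TSV; round-trip safe."""
    path = Path(path)
    fmt = format or ("graphml" if path.suffix == ".graphml" else "tsv")
    if fmt == "graphml":
        nx.write_graphml(net.graph, str(path))
    elif fmt == "tsv":
        cls = nx.get_node_attributes(net.graph, "concept_class")
        lines = [f"{u}\t{cls[u]}\t{v}\t{cls[v]}\t{d['cosine_distance']!r}"
                 for u, v, d in sorted(net.graph.edges(data=True))]
        path.write_text("\n".join(lines) + ("\n" if lines else ""),
                        encoding="utf-8")
    else:
        raise ValueError(f"unsupported export format {format!r}")
    return path


def load_network(path: str | Path, theta: float, class_pair,
                 format: str | None = None) -> SemanticNetwork:
    path = Path(path)
    fmt = format or ("graphml" if path.suffix == ".graphml" else "tsv")
    cls_a, cls_b = _normalize_pair(class_pair)
    if fmt == "graphml":
        g = nx.read_graphml(str(path))
        g = nx.Graph(g)
    elif fmt == "tsv":
        g = nx.Graph()
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line.strip():
                continue
            u, cu, v, cv, d = line.split("\t")
            g.add_node(u, concept_class=cu)
            g.add_node(v, concept_class=cv)
            g.add_edge(u, v, cosine_distance=float(d))
    else:
        raise ValueError(f"unsupported format {format!r}")
    return SemanticNetwork(theta=theta, class_pair=(cls_a, cls_b), graph=g)
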