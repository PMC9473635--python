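"""Skip-gram word embeddings and cosine similarity/distance.

The trainer learns one dense vector per vocabulary token from the
phrase-fused corpus using skip-gram with negative sampling. Defaults match
the configuration used throughout this package's analyses: 100-dimensional
vectors, 10 epochs, initial learning rate 0.025, context window 5, minimum
corpus frequency 3, 5 negative samples. Training is single-worker and
seeded, so a fixed seed reproduces vectors bitwise.

Relatedness between terms is measured by cosine similarity
``u.v / (|u| |v|)``; *cosine distance* here is ``1 - similarity``, so 0
means identical direction and values near 1 mean unrelated.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import Counter
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._sgns import train_sgns
from .corpus import TokenizedDocument
from .tagging import fused_token

logger = logging.getLogger(__name__)

_NEG_TABLE_SIZE = 250_000
_NEG_POWER = 0.75


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the skip-gram trainer."""

    vector_length: int = 100
    epochs: int = 10
    initial_learning_rate: float = 0.025
    window: int = 5
    min_count: int = 3
    negative_samples: int = 5
    min_learning_rate: float = 1e-4
    seed: int = 1
    workers: int = 1  # >1 would trade bitwise reproducibility for speed

    def __post_init__(self) -> None:
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if self.vector_length < 1 or self.epochs < 1 or self.window < 1:
            raise ValueError("vector_length, epochs and window must be >= 1")


@dataclass
class EmbeddingModel:
    """token -> vector map plus the configuration that produced it."""

    vectors: np.ndarray  # float32 (V, D)
    index: dict[str, int]  # token -> row
    config: TrainingConfig
    corpus_fingerprint: str = ""

    def __post_init__(self) -> None:
        if self.vectors.ndim != 2 or len(self.index) != self.vectors.shape[0]:
            raise ValueError("index size must match vector matrix rows")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding vectors contain non-finite components")

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def __len__(self) -> int:
        return len(self.index)

    @property
    def vocab(self) -> list[str]:
        return list(self.index)

    def vector(self, token: str) -> np.ndarray | None:
        """The raw token's vector, or None if it is out of vocabulary."""
        i = self.index.get(token)
        return None if i is None else self.vectors[i]

    def term_vector(self, term: str) -> np.ndarray | None:
        """Vector for a canonical concept term (multiword terms are looked
        up by their fused underscore form); None when the term never met
        the minimum corpus frequency."""
        return self.vector(fused_token(term))

    @classmethod
    def from_vectors(cls, mapping: dict[str, np.ndarray],
                     config: TrainingConfig | None = None) -> "EmbeddingModel":
        """Build a model directly from a token->vector dict (hand-set
        vectors for small exact tests and toy networks)."""
        tokens = list(mapping)
        mat = np.asarray([mapping[t] for t in tokens], dtype=np.float32)
        if config is None:
            config = TrainingConfig(vector_length=mat.shape[1])
        return cls(vectors=mat, index={t: i for i, t in enumerate(tokens)},
                   config=config, corpus_fingerprint="hand-set")

    # -- persistence --------------------------------------------------------

    def save(self, prefix: str | Path) -> list[Path]:
        """Write ``<prefix>.vec`` (word2vec text format) and a JSON sidecar."""
        prefix = Path(prefix)
        vec_path = prefix.with_suffix(".vec")
        with vec_path.open("w", encoding="utf-8") as fh:
            fh.write(f"{self.vectors.shape[0]} {self.vectors.shape[1]}\n")
            for token, i in self.index.items():
                row = " ".join(repr(float(x)) for x in self.vectors[i])
                fh.write(f"{token} {row}\n")
        side_path = prefix.with_suffix(".json")
        side_path.write_text(json.dumps(
            {"config": asdict(self.config),
             "corpus_fingerprint": self.corpus_fingerprint}, indent=2) + "\n",
            encoding="utf-8")
        return [vec_path, side_path]

    @classmethod
    def load(cls, prefix: str | Path) -> "EmbeddingModel":
        prefix = Path(prefix)
        side = json.loads(prefix.with_suffix(".json").read_text("utf-8"))
        config = TrainingConfig(**side["config"])
        index: dict[str, int] = {}
        with prefix.with_suffix(".vec").open(encoding="utf-8") as fh:
            n, d = (int(x) for x in fh.readline().split())
            mat = np.empty((n, d), dtype=np.float32)
            for i, line in enumerate(fh):
                parts = line.rstrip("\n").split(" ")
                index[parts[0]] = i
                mat[i] = np.asarray(parts[1:], dtype=np.float32)
        return cls(vectors=mat, index=index, config=config,
                   corpus_fingerprint=side["corpus_fingerprint"])


def _fingerprint(docs: Sequence[TokenizedDocument]) -> str:
    h = hashlib.sha256()
    for doc in docs:
        h.update("\x1f".join(doc.tokens).encode("utf-8"))
        h.update(b"\x1e")
    return h.hexdigest()


def train_embeddings(docs: Sequence[TokenizedDocument],
                     config: TrainingConfig | None = None,
                     **overrides) -> EmbeddingModel:
    """Train skip-gram embeddings on tokenized (phrase-fused) documents.

    Tokens below ``min_count`` corpus frequency are dropped from the
    vocabulary before training. Raises on an empty corpus or when the
    min-count filter empties the vocabulary.
    """
    if config is None:
        config = TrainingConfig()
    if overrides:
        config = replace(config, **overrides)
    if not any(doc.tokens for doc in docs):
        raise ValueError("cannot train embeddings on an empty corpus")

    counts = Counter()
    for doc in docs:
        counts.update(doc.tokens)
    kept = sorted((t for t, c in counts.items() if c >= config.min_count),
                  key=lambda t: (-counts[t], t))
    if not kept:
        raise ValueError("empty vocabulary: every token is below min_count")
    index = {t: i for i, t in enumerate(kept)}

    # encode the corpus, dropping out-of-vocabulary tokens
    ids: list[np.ndarray] = []
    offsets = [0]
    for doc in docs:
        enc = np.asarray([index[t] for t in doc.tokens if t in index],
                         dtype=np.int32)
        if len(enc):
            ids.append(enc)
            offsets.append(offsets[-1] + len(enc))
    data = np.concatenate(ids) if ids else np.empty(0, dtype=np.int32)
    offsets_arr = np.asarray(offsets, dtype=np.int64)

    # unigram^0.75 negative-sampling table
    freqs = np.asarray([counts[t] for t in kept], dtype=np.float64)
    weights = freqs ** _NEG_POWER
    cum = np.cumsum(weights / weights.sum())
    table = np.searchsorted(
        cum, (np.arange(_NEG_TABLE_SIZE) + 0.5) / _NEG_TABLE_SIZE
    ).astype(np.int32)

    rng = np.random.RandomState(config.seed % (2 ** 31))
    dim = config.vector_length
    syn0 = ((rng.rand(len(kept), dim) - 0.5) / dim).astype(np.float32)
    syn1 = np.zeros((len(kept), dim), dtype=np.float32)

    logger.info("training SGNS: %d docs, %d tokens, vocab %d, dim %d",
                len(offsets_arr) - 1, len(data), len(kept), dim)
    train_sgns(data, offsets_arr, syn0, syn1, table,
               config.window, config.negative_samples,
               config.initial_learning_rate, config.min_learning_rate,
               config.epochs, config.seed)

    return EmbeddingModel(vectors=syn0, index=index, config=config,
                          corpus_fingerprint=_fingerprint(docs))


# ---------------------------------------------------------------------------
# cosine measures
# ---------------------------------------------------------------------------

def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """u.v / (|u| |v|), in [-1, 1]. Raises on zero vectors."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"vector length mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 - cosine_similarity, in [0, 2]; low distance = related terms."""
    return 1.0 - cosine_similarity(u, v)
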