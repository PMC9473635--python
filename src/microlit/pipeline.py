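"""End-to-end orchestration from a single declarative configuration.

Two entry points mirror the two analyses: :func:`run_geo_pipeline`
(ingest -> country tallies -> continent/income rollups -> scatter table)
and :func:`run_semantic_pipeline` (ingest -> tag & fuse -> train
embeddings -> networks, sweeps and reference coverage).

Every output CSV starts with a ``# provenance:`` header carrying the
input hashes, the effective configuration, the seed and the tool version,
and each run writes a manifest of output-file hashes. Nothing in the
outputs depends on wall-clock time, so a rerun with an identical
configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .corpus import Corpus, load_corpus, preprocess_corpus
from .embedding import EmbeddingModel, TrainingConfig, train_embeddings
from .geo import (Gazetteer, aggregate, scatter_table,
                  tally_articles_by_country, tally_authors_by_country)
from .network import (DEFAULT_GRID, CLASS_PAIRS, ReferenceEdgeSet,
                      build_network, coverage_against_reference,
                      export_network, sweep_thresholds)
from .tagging import fuse_corpus, load_dictionaries

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    corpus: str
    out_dir: str
    gazetteer: str | None = None
    country_meta: str | None = None
    dictionaries: tuple[str, ...] = ()
    reference: str | None = None
    theta: float = 0.35
    grid: tuple[float, ...] = DEFAULT_GRID
    training: dict = field(default_factory=dict)
    seed: int = 1
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text(encoding="utf-8")
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        if "dictionaries" in raw:
            raw["dictionaries"] = tuple(raw["dictionaries"])
        if "grid" in raw:
            raw["grid"] = tuple(raw["grid"])
        return cls(**raw)

    def validate(self, *, need_gazetteer: bool = False,
                 need_dictionaries: bool = False) -> None:
        """Check that every referenced input exists before any compute."""
        paths = [self.corpus, *self.dictionaries]
        if self.gazetteer:
            paths.append(self.gazetteer)
        if self.country_meta:
            paths.append(self.country_meta)
        if self.reference:
            paths.append(self.reference)
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(
                "config references missing input(s): " + ", ".join(missing))
        if need_gazetteer and self.gazetteer and not self.country_meta:
            logger.warning("gazetteer given without country metadata; "
                           "rollups will use 'Not classified'")
        if need_dictionaries and not self.dictionaries:
            raise ValueError("semantic pipeline requires dictionary paths")

    def training_config(self) -> TrainingConfig:
        return TrainingConfig(seed=self.seed, **self.training)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _provenance(config: RunConfig) -> str:
    inputs = {}
    for p in [config.corpus, *config.dictionaries,
              config.gazetteer, config.country_meta, config.reference]:
        if p:
            inputs[str(p)] = _sha256(Path(p))
    block = {"tool": f"microlit {__version__}", "seed": config.seed,
             "config": dataclasses.asdict(config), "inputs": inputs}
    return json.dumps(block, sort_keys=True)


class _Writer:
    """Collects output files; cleans up partial output on stage failure."""

    def __init__(self, out_dir: Path, provenance: str):
        self.out_dir = out_dir
        self.provenance = provenance
        self.written: list[Path] = []
        out_dir.mkdir(parents=True, exist_ok=True)

    def csv(self, name: str, frame: pd.DataFrame, **to_csv_kw) -> Path:
        path = self.out_dir / name
        with path.open("w", encoding="utf-8") as fh:
            fh.write(f"# provenance: {self.provenance}\n")
            frame.to_csv(fh, index=False, lineterminator="\n", **to_csv_kw)
        self.written.append(path)
        return path

    def add(self, path: Path) -> Path:
        self.written.append(path)
        return path

    def manifest(self, name: str) -> dict[str, str]:
        manifest = {p.name: _sha256(p) for p in sorted(self.written)}
        path = self.out_dir / name
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n",
                        encoding="utf-8")
        return manifest

    def cleanup(self) -> None:
        for p in self.written:
            p.unlink(missing_ok=True)


def _load_gazetteer(config: RunConfig) -> Gazetteer:
    if config.gazetteer:
        return Gazetteer.from_tsv(config.gazetteer, config.country_meta)
    return Gazetteer.default()


def _counts_frame(counts: dict[str, int], key: str) -> pd.DataFrame:
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=[key, "count"])


def run_geo_pipeline(config: RunConfig) -> dict[str, str]:
    """Mention tally, author tally, continent/income rollups, scatter CSV."""
    config.validate(need_gazetteer=True)
    writer = _Writer(Path(config.out_dir), _provenance(config))
    try:
        stage = "ingest"
        corpus = load_corpus(config.corpus)
        gaz = _load_gazetteer(config)
        stage = "tally"
        mentions = tally_articles_by_country(corpus, gaz)
        authors = tally_authors_by_country(corpus, gaz)
        stage = "report"
        writer.csv("country_mentions.csv",
                   _counts_frame(mentions.counts, "country"))
        writer.csv("country_authors.csv",
                   _counts_frame(authors.counts, "country"))
        rollups = []
        for kind, tally in (("article_mentions", mentions),
                            ("unique_authors", authors)):
            for level in ("continent", "income"):
                for group, n in sorted(aggregate(tally, level, gaz).items()):
                    rollups.append({"track": kind, "level": level,
                                    "group": group, "count": n})
        frame = pd.DataFrame(rollups,
                             columns=["track", "level", "group", "count"])
        writer.csv("continent_rollup.csv",
                   frame[frame.level == "continent"])
        writer.csv("income_rollup.csv", frame[frame.level == "income"])
        writer.csv("scatter.csv", scatter_table(mentions, authors, gaz))
    except Exception as exc:
        writer.cleanup()
        raise RuntimeError(f"geo pipeline failed at stage {stage!r}: {exc}") \
            from exc
    return writer.manifest("geo_manifest.json")


def run_semantic_pipeline(config: RunConfig) -> dict[str, str]:
    """Tag & fuse, train embeddings, then networks, sweeps and coverage."""
    config.validate(need_dictionaries=True)
    writer = _Writer(Path(config.out_dir), _provenance(config))
    try:
        stage = "ingest"
        corpus = load_corpus(config.corpus)
        dicts = load_dictionaries(config.dictionaries)
        stage = "tag+fuse"
        docs = fuse_corpus(preprocess_corpus(corpus), dicts)
        stage = "embed"
        model = train_embeddings(docs, config.training_config())
        for p in model.save(writer.out_dir / "embeddings"):
            writer.add(p)
        terms_by_class = {d.concept_class: d.canonical_terms for d in dicts}
        stage = "network"
        for cls_a, cls_b in CLASS_PAIRS:
            if not (terms_by_class.get(cls_a) and terms_by_class.get(cls_b)):
                continue
            tag = f"{cls_a}-{cls_b}"
            net = build_network(model, terms_by_class, (cls_a, cls_b),
                                config.theta)
            writer.add(export_network(
                net, writer.out_dir / f"network_{tag}.graphml"))
            writer.add(export_network(
                net, writer.out_dir / f"network_{tag}.tsv"))
            sweep = sweep_thresholds(model, terms_by_class, (cls_a, cls_b),
                                     config.grid)
            writer.csv(f"sweep_{tag}.csv", sweep.to_frame())
        stage = "coverage"
        if config.reference:
            ref = ReferenceEdgeSet.from_tsv(config.reference)
            report = coverage_against_reference(model, ref, config.grid)
            writer.csv("coverage.csv", report.to_frame())
            summary = writer.out_dir / "coverage.json"
            summary.write_text(json.dumps(
                {"n_reference": report.n_reference,
                 "n_mappable": report.n_mappable,
                 "n_unmappable": report.n_unmappable,
                 "coverage_fraction_at": {str(k): v for k, v in
                                          report.coverage_fraction_at.items()}},
                indent=2, sort_keys=True) + "\n", encoding="utf-8")
            writer.add(summary)
    except Exception as exc:
        writer.cleanup()
        raise RuntimeError(
            f"semantic pipeline failed at stage {stage!r}: {exc}") from exc
    return writer.manifest("semantic_manifest.json")
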