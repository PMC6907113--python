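"""End-to-end retrieval pipelines: index -> first pass -> feedback ->
expansion -> second pass -> evaluation.

The named expansion models are ``rocchio`` (classic, BM25 first pass),
``hroc1/2/3`` (HAL-augmented, fixed window, one per normalization) and
``hroc_ap1/2/3`` (norm1 with the f1/f2/f3 adaptive window).  Every run
can capture a manifest (config snapshot, seed, inputs, outputs) so runs
are reproducible and diff-stable: identical inputs and config yield
byte-identical run files.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from . import __version__
from .corpus import AnalyzerConfig, CorpusIndex, DEFAULT_ANALYZER, TokenizedDocument, build_index, tokenize
from .evaluation import MetricReport, Qrels, evaluate_run
from .expansion import HRocConfig, hroc_expand, rocchio_expand, second_pass
from .hal import WindowSpec
from .query import WeightedQuery
from .retrieval import BM25Params, DEFAULT_CUTOFF, DirichletParams, RunRanking, retrieve
from .trec import Topic, read_corpus, write_run

__all__ = [
    "EXPANSION_MODELS",
    "RunManifest",
    "index_corpus",
    "topics_to_queries",
    "search",
    "expand_search",
    "evaluate",
]

EXPANSION_MODELS = (
    "rocchio",
    "hroc1",
    "hroc2",
    "hroc3",
    "hroc_ap1",
    "hroc_ap2",
    "hroc_ap3",
)


@dataclass
class RunManifest:
    """Reproducibility record attached to a produced run file."""

    model: str
    config: dict
    inputs: dict
    outputs: dict
    seed: int | None = None
    version: str = __version__
    created: float = field(default_factory=time.time)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


def index_corpus(
    source: str | Path | Iterable[tuple[str, str]],
    analyzer: AnalyzerConfig = DEFAULT_ANALYZER,
) -> CorpusIndex:
    """Tokenize and index a corpus path (txt dir / jsonl) or (id, text) stream."""
    if isinstance(source, (str, Path)):
        source = read_corpus(source)
    return build_index(
        TokenizedDocument(doc_id, tokenize(text, analyzer)) for doc_id, text in source
    )


def topics_to_queries(
    topics: Sequence[Topic],
    analyzer: AnalyzerConfig = DEFAULT_ANALYZER,
    field_priority: Sequence[str] = ("note", "description"),
) -> list[WeightedQuery]:
    return [
        WeightedQuery.from_text(t.topic_id, t.query_text(field_priority), analyzer)
        for t in topics
    ]


def search(
    index: CorpusIndex,
    queries: Sequence[WeightedQuery],
    model: str = "bm25",
    params: BM25Params | DirichletParams | None = None,
    cutoff: int = DEFAULT_CUTOFF,
) -> list[RunRanking]:
    """First-pass retrieval for every query."""
    return [retrieve(q, index, model, params, cutoff) for q in queries]


def _resolve_model(model: str, config: HRocConfig) -> HRocConfig:
    if model in ("hroc1", "hroc2", "hroc3"):
        return replace(config, norm_method=f"norm{model[-1]}")
    if model in ("hroc_ap1", "hroc_ap2", "hroc_ap3"):
        window = WindowSpec(mode="adaptive", adaptive_variant=f"f{model[-1]}")
        return replace(config, norm_method="norm1", window=window)
    raise ValueError(f"unknown expansion model: {model!r} (expected one of {EXPANSION_MODELS})")


def expand_search(
    index: CorpusIndex,
    queries: Sequence[WeightedQuery],
    model: str = "hroc1",
    config: HRocConfig = HRocConfig(),
    params: BM25Params = BM25Params(),
    cutoff: int = DEFAULT_CUTOFF,
) -> list[RunRanking]:
    """Full PRF pipeline for every query.

    First pass (BM25) -> top-|R| feedback documents -> expansion
    (Rocchio or an HRoc variant) -> BM25 second pass with the expanded
    weights as fractional query term frequencies.
    """
    if model not in EXPANSION_MODELS:
        raise ValueError(f"unknown expansion model: {model!r} (expected one of {EXPANSION_MODELS})")
    runs = []
    for q0 in queries:
        first = retrieve(q0, index, "bm25", params, cutoff)
        feedback = [index.docs[d] for d in first.top(config.n_feedback_docs)]
        if not feedback:
            runs.append(first)  # nothing retrieved: keep the (empty) first pass
            continue
        if model == "rocchio":
            expanded = rocchio_expand(
                q0,
                feedback,
                index,
                alpha=1.0,
                beta=config.beta,
                params=params,
                n_expansion_terms=config.n_expansion_terms,
            )
        else:
            expanded = hroc_expand(q0, feedback, _resolve_model(model, config), index, params)
        runs.append(second_pass(expanded, index, params, cutoff))
    return runs


def evaluate(
    runs: Sequence[RunRanking],
    qrels: Qrels,
    cutoff: int = DEFAULT_CUTOFF,
) -> MetricReport:
    return evaluate_run(runs, qrels, cutoff)


def run_to_file(
    runs: Sequence[RunRanking],
    path: str | Path,
    tag: str,
    manifest: RunManifest | None = None,
) -> None:
    """Write a TREC run plus (optionally) its manifest next to it."""
    write_run(runs, path, tag)
    if manifest is not None:
        manifest.outputs["run"] = str(path)
        manifest.save(Path(path).with_suffix(".manifest.json"))
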