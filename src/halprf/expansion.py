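"""Pseudo-relevance-feedback query expansion: Rocchio and HRoc.

Classic Rocchio reformulates the query as a linear combination of the
original vector and the centroid of the feedback-document term vectors:

    Q1 = α·Q0 + β·Σ_{r in R} r / |R|

where r holds per-term feedback weights (here the document-side BM25
weight (k1+1)·tf/(K+tf)·IDF — the query-side saturation factor is
meaningless for terms not in the query).

HRoc mixes in a second, proximity-based component built from HAL
sliding-window co-occurrence with the query terms, with each component
normalized across the candidate axis so the two are commensurable:

    Q' = (1−α)·Q0 + α·[ (1−β)·Norm(mean_R r) + β·Norm(mean_R W_HAL) ]

Candidates are all feedback-document terms minus the original query
terms, ranked by the bracketed combined score (after normalization),
truncated to the configured number of expansion terms, then merged with
Q0.  Three normalizations are supported:

    norm1: (t − min) / (max − min)        (min-max)
    norm2: t / sqrt(Σ t²)                 (unit L2)
    norm3: t / max                        (max-scaling)

HRoc1/2/3 are this one engine parameterized by norm_method; the _AP
variants replace the fixed window size D with a per-feedback-document
adaptive size (see :mod:`halprf.hal`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .corpus import CorpusIndex, TokenizedDocument, idf
from .hal import WindowSpec, w_hal_vector, window_size
from .query import WeightedQuery
from .retrieval import BM25Params, DEFAULT_CUTOFF, RunRanking, retrieve

__all__ = [
    "HRocConfig",
    "rocchio_expand",
    "bm25_feedback_weight",
    "normalize",
    "feedback_term_table",
    "hroc_expand",
    "second_pass",
]

logger = logging.getLogger(__name__)

NORM_METHODS = ("norm1", "norm2", "norm3")


@dataclass(frozen=True)
class HRocConfig:
    """Hyper-parameters of the HRoc expansion engine.

    alpha balances original query vs. feedback information; beta balances
    the frequency-based (BM25) vs. proximity-based (HAL) feedback
    components.  Both live in [0, 1].
    """

    alpha: float = 0.5
    beta: float = 0.5
    n_feedback_docs: int = 10
    n_expansion_terms: int = 10
    window: WindowSpec = field(default_factory=WindowSpec)
    norm_method: str = "norm1"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must be in [0, 1], got {self.beta}")
        if self.n_feedback_docs < 1:
            raise ValueError("n_feedback_docs must be >= 1")
        if self.n_expansion_terms < 1:
            raise ValueError("n_expansion_terms must be >= 1")
        if self.norm_method not in NORM_METHODS:
            raise ValueError(f"unknown norm_method: {self.norm_method!r}")


def bm25_feedback_weight(
    term: str,
    feedback_doc: TokenizedDocument,
    index: CorpusIndex,
    params: BM25Params = BM25Params(),
) -> float:
    """Document-side BM25 weight of ``term`` in one feedback document."""
    tf = feedback_doc.tokens.count(term)
    if tf == 0:
        return 0.0
    k = params.k1 * ((1.0 - params.b) + params.b * feedback_doc.dl / index.avg_dl)
    return (params.k1 + 1.0) * tf / (k + tf) * idf(term, index)


def _bm25_doc_vector(
    doc: TokenizedDocument, index: CorpusIndex, params: BM25Params
) -> dict[str, float]:
    k = params.k1 * ((1.0 - params.b) + params.b * doc.dl / index.avg_dl)
    tf: dict[str, int] = {}
    for tok in doc.tokens:
        tf[tok] = tf.get(tok, 0) + 1
    return {
        t: (params.k1 + 1.0) * n / (k + n) * idf(t, index)
        for t, n in tf.items()
    }


def _mean_vectors(vectors: list[dict[str, float]]) -> dict[str, float]:
    """Per-term arithmetic mean over |R| vectors (absent term = 0)."""
    out: dict[str, float] = {}
    for vec in vectors:
        for term, w in vec.items():
            out[term] = out.get(term, 0.0) + w
    n = len(vectors)
    return {t: w / n for t, w in out.items()}


def normalize(scores: dict[str, float], method: str) -> dict[str, float]:
    """Rescale a term-score map by one of the three normalizations.

    Degenerate inputs never raise: min-max with max == min, or an
    all-zero vector under norm2/norm3, yield an all-zero output (with a
    logged warning for the min-max case).
    """
    if not scores:
        raise ValueError("cannot normalize an empty score map")
    values = list(scores.values())
    if method == "norm1":
        lo, hi = min(values), max(values)
        if hi == lo:
            logger.warning("norm1 on a constant vector (max == min); returning zeros")
            return {t: 0.0 for t in scores}
        return {t: (v - lo) / (hi - lo) for t, v in scores.items()}
    if method == "norm2":
        norm = math.sqrt(sum(v * v for v in values))
        if norm == 0.0:
            return {t: 0.0 for t in scores}
        return {t: v / norm for t, v in scores.items()}
    if method == "norm3":
        hi = max(values)
        if hi == 0.0:
            return {t: 0.0 for t in scores}
        return {t: v / hi for t, v in scores.items()}
    raise ValueError(f"unknown norm method: {method!r}")


def rocchio_expand(
    q0: WeightedQuery,
    feedback_docs: list[TokenizedDocument],
    index: CorpusIndex,
    alpha: float = 1.0,
    beta: float = 0.5,
    params: BM25Params = BM25Params(),
    n_expansion_terms: int | None = None,
    norm_method: str | None = None,
    include_query_terms: bool = True,
) -> WeightedQuery:
    """Classic Rocchio expansion Q1 = α·Q0 + β·centroid(R).

    The centroid of the feedback-document BM25 term vectors is truncated
    to the top ``n_expansion_terms`` non-query candidates (ties broken
    lexicographically) before merging.  ``include_query_terms`` controls
    whether original query terms also receive their centroid contribution
    (the classic behaviour); disabling it, together with ``norm_method``,
    gives the normalized-Rocchio variant that HRoc reduces to at beta=0.
    """
    if not feedback_docs:
        raise ValueError("empty feedback set")
    centroid = _mean_vectors([_bm25_doc_vector(d, index, params) for d in feedback_docs])
    candidates = {t: w for t, w in centroid.items() if t not in q0.weights}
    if norm_method is not None and candidates:
        candidates = normalize(candidates, norm_method)
    k = n_expansion_terms if n_expansion_terms is not None else len(candidates)
    chosen = sorted(candidates.items(), key=lambda e: (-e[1], e[0]))[:k]
    weights = {t: alpha * w for t, w in q0.weights.items()}
    if include_query_terms:
        for t in q0.weights:
            if t in centroid:
                weights[t] = weights.get(t, 0.0) + beta * centroid[t]
    for t, w in chosen:
        weights[t] = weights.get(t, 0.0) + beta * w
    return WeightedQuery(q0.topic_id, weights)


def _hroc_components(
    q0: WeightedQuery,
    feedback_docs: list[TokenizedDocument],
    config: HRocConfig,
    index: CorpusIndex,
    params: BM25Params,
) -> tuple[dict[str, float], dict[str, float]]:
    """Mean BM25 and mean W_HAL candidate vectors over the feedback set."""
    bm25_vecs: list[dict[str, float]] = []
    hal_vecs: list[dict[str, float]] = []
    for doc in feedback_docs:
        bm25_vecs.append(_bm25_doc_vector(doc, index, params))
        d = window_size(config.window, doc.dl, index.avg_dl)
        hal_vecs.append(w_hal_vector(doc, q0, d, index))
    mean_bm25 = _mean_vectors(bm25_vecs)
    mean_hal = _mean_vectors(hal_vecs)
    drop = set(q0.weights)
    mean_bm25 = {t: w for t, w in mean_bm25.items() if t not in drop}
    # HAL candidates are a subset of the feedback vocabulary by construction
    mean_hal = {t: mean_hal.get(t, 0.0) for t in mean_bm25}
    return mean_bm25, mean_hal


def feedback_term_table(
    q0: WeightedQuery,
    feedback_docs: list[TokenizedDocument],
    config: HRocConfig,
    index: CorpusIndex,
    params: BM25Params = BM25Params(),
) -> pd.DataFrame:
    """Explain-mode table of candidate scores before and after normalization.

    Columns: bm25_raw, hal_raw, bm25_norm, hal_norm, combined; sorted by
    the combined bracketed score used for candidate selection.
    """
    mean_bm25, mean_hal = _hroc_components(q0, feedback_docs, config, index, params)
    if not mean_bm25:
        return pd.DataFrame(
            columns=["bm25_raw", "hal_raw", "bm25_norm", "hal_norm", "combined"]
        )
    bm25_norm = normalize(mean_bm25, config.norm_method)
    hal_norm = normalize(mean_hal, config.norm_method)
    rows = {
        t: (
            mean_bm25[t],
            mean_hal[t],
            bm25_norm[t],
            hal_norm[t],
            (1.0 - config.beta) * bm25_norm[t] + config.beta * hal_norm[t],
        )
        for t in mean_bm25
    }
    table = pd.DataFrame.from_dict(
        rows,
        orient="index",
        columns=["bm25_raw", "hal_raw", "bm25_norm", "hal_norm", "combined"],
    )
    return table.sort_values("combined", ascending=False)


def hroc_expand(
    q0: WeightedQuery,
    feedback_docs: list[TokenizedDocument],
    config: HRocConfig,
    index: CorpusIndex,
    params: BM25Params = BM25Params(),
) -> WeightedQuery:
    """HAL-augmented Rocchio expansion (Eqs. above).

    alpha = 0 returns Q0 unchanged; an all-zero proximity component falls
    back to the pure-BM25 branch (beta = 0) with a warning.
    """
    if not feedback_docs:
        raise ValueError("empty feedback set")
    if config.alpha == 0.0:
        return WeightedQuery(q0.topic_id, dict(q0.weights))
    mean_bm25, mean_hal = _hroc_components(q0, feedback_docs, config, index, params)
    if not mean_bm25:
        logger.warning("topic %s: no candidate terms in feedback set", q0.topic_id)
        return WeightedQuery(q0.topic_id, {t: (1 - config.alpha) * w for t, w in q0.weights.items()})
    beta = config.beta
    if beta > 0.0 and all(v == 0.0 for v in mean_hal.values()):
        logger.warning(
            "topic %s: all HAL components zero; falling back to pure BM25 feedback",
            q0.topic_id,
        )
        beta = 0.0
    bm25_norm = normalize(mean_bm25, config.norm_method)
    hal_norm = normalize(mean_hal, config.norm_method)
    combined = {
        t: (1.0 - beta) * bm25_norm[t] + beta * hal_norm[t] for t in mean_bm25
    }
    chosen = sorted(combined.items(), key=lambda e: (-e[1], e[0]))[: config.n_expansion_terms]
    weights = {t: (1.0 - config.alpha) * w for t, w in q0.weights.items()}
    for t, w in chosen:
        weights[t] = weights.get(t, 0.0) + config.alpha * w
    return WeightedQuery(q0.topic_id, weights)


def second_pass(
    query_expanded: WeightedQuery,
    index: CorpusIndex,
    params: BM25Params = BM25Params(),
    cutoff: int = DEFAULT_CUTOFF,
) -> RunRanking:
    """Re-retrieve with the expanded query.

    BM25 with the expansion weights used as fractional within-query term
    frequencies; tie-breaking as in the first pass, so runs stay
    deterministic.
    """
    return retrieve(query_expanded, index, "bm25", params, cutoff)
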