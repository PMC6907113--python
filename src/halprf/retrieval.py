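"""First-pass document ranking: Okapi BM25 and Dirichlet-smoothed LM.

BM25 scores a document D for query term q as

    w(q, D) = (k1+1)·tf / (K + tf) · (k3+1)·qtf / (k3 + qtf)
              · log((N − df + 0.5) / (df + 0.5)),
    K = k1·((1−b) + b·dl/avdl)

with the IDF floored at 0 for very common terms.  Note the query-side
saturation factor: some sources print the denominator as k3·qtf, which is
constant in qtf and inconsistent with the Okapi literature; the standard
k3 + qtf form is the default here and the printed variant is available as
an audit mode (``BM25Params(as_printed=True)``).

The language model ranks by query likelihood with a Dirichlet prior of
mass mu:  score = Σ_q qtf · log p(q|D),
p(q|D) = (c(q,D) + mu·p(q|C)) / (|D| + mu).  Query terms absent from the
whole collection are skipped (they carry no information) rather than
contributing −inf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .corpus import CorpusIndex, idf
from .query import WeightedQuery

__all__ = [
    "BM25Params",
    "DirichletParams",
    "RunRanking",
    "bm25_term_weight",
    "score_bm25",
    "score_dirichlet",
    "retrieve",
]

DEFAULT_CUTOFF = 1000


@dataclass(frozen=True)
class BM25Params:
    k1: float = 1.2
    k3: float = 8.0
    b: float = 0.5
    as_printed: bool = False  # audit mode: query factor (k3+1)qtf/(k3·qtf)

    def __post_init__(self) -> None:
        if not 0.0 <= self.b <= 1.0:
            raise ValueError(f"b must be in [0, 1], got {self.b}")
        if self.k1 <= 0 or self.k3 <= 0:
            raise ValueError("k1 and k3 must be positive")


@dataclass(frozen=True)
class DirichletParams:
    mu: float = 2000.0

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError(f"mu must be non-negative, got {self.mu}")


@dataclass
class RunRanking:
    """Per-topic ranked list of (doc_id, score), descending score."""

    topic_id: str
    entries: list[tuple[str, float]] = field(default_factory=list)
    cutoff: int = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        seen = set()
        for doc_id, _ in self.entries:
            if doc_id in seen:
                raise ValueError(f"duplicate doc_id in ranking: {doc_id!r}")
            seen.add(doc_id)
        scores = [s for _, s in self.entries]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("ranking scores must be non-increasing")
        if len(self.entries) > self.cutoff:
            raise ValueError("ranking longer than its cutoff")

    @property
    def doc_ids(self) -> list[str]:
        return [d for d, _ in self.entries]

    def top(self, n: int) -> list[str]:
        return self.doc_ids[:n]


def bm25_term_weight(
    tf: float,
    qtf: float,
    dl: float,
    params: BM25Params,
    n_docs: int,
    df: int,
    avg_dl: float,
) -> float:
    """BM25 weight of one query term in one document."""
    if df > n_docs:
        raise ValueError(f"df ({df}) exceeds collection size ({n_docs})")
    if tf <= 0 or qtf <= 0:
        return 0.0
    k = params.k1 * ((1.0 - params.b) + params.b * dl / avg_dl)
    doc_side = (params.k1 + 1.0) * tf / (k + tf)
    if params.as_printed:
        query_side = (params.k3 + 1.0) * qtf / (params.k3 * qtf)
    else:
        query_side = (params.k3 + 1.0) * qtf / (params.k3 + qtf)
    w_idf = max(0.0, math.log((n_docs - df + 0.5) / (df + 0.5)))
    return doc_side * query_side * w_idf


def score_bm25(
    query: WeightedQuery,
    doc_id: str,
    index: CorpusIndex,
    params: BM25Params = BM25Params(),
) -> float:
    """Sum of BM25 term weights over query terms present in the document."""
    if not query.weights:
        raise ValueError("empty query")
    dl = index.dl(doc_id)
    total = 0.0
    for term, qtf in query.weights.items():
        if qtf <= 0:
            continue
        tf = index.tf(term, doc_id)
        if tf == 0:
            continue
        total += bm25_term_weight(
            tf, qtf, dl, params, index.n_docs, index.df(term), index.avg_dl
        )
    return total


def score_dirichlet(
    query: WeightedQuery,
    doc_id: str,
    index: CorpusIndex,
    params: DirichletParams = DirichletParams(),
) -> float:
    """Query log-likelihood under the Dirichlet-smoothed document model."""
    if not query.weights:
        raise ValueError("empty query")
    dl = index.dl(doc_id)
    total = 0.0
    for term, qtf in query.weights.items():
        if qtf <= 0:
            continue
        p_c = index.p_collection(term)
        if p_c == 0.0:
            continue  # unseen in collection: skipped, never -inf
        c_wd = index.tf(term, doc_id)
        p_wd = (c_wd + params.mu * p_c) / (dl + params.mu)
        if p_wd <= 0.0:  # mu = 0 and term absent from this document
            return -math.inf
        total += qtf * math.log(p_wd)
    return total


def _candidate_docs(query: WeightedQuery, index: CorpusIndex) -> list[str]:
    seen: set[str] = set()
    for term in query.weights:
        for posting in index.postings.get(term, ()):
            seen.add(posting.doc_id)
    return sorted(seen)


def retrieve(
    query: WeightedQuery,
    index: CorpusIndex,
    model: str = "bm25",
    params: BM25Params | DirichletParams | None = None,
    cutoff: int = DEFAULT_CUTOFF,
) -> RunRanking:
    """Rank the top-``cutoff`` documents for ``query``.

    BM25 scores only documents sharing at least one query term (others
    score 0 and are not retrieved); the language model scores every
    document, since smoothing gives term-absent documents a finite score.
    Ties are broken lexicographically by doc_id, so runs are deterministic.
    """
    if index.n_docs == 0:
        raise ValueError("empty index")
    if not query.weights:
        raise ValueError("empty query")
    if model == "bm25":
        bm_params = params if isinstance(params, BM25Params) else BM25Params()
        scored = [
            (doc_id, score_bm25(query, doc_id, index, bm_params))
            for doc_id in _candidate_docs(query, index)
        ]
        scored = [(d, s) for d, s in scored if s > 0.0]
    elif model == "dirichlet":
        lm_params = params if isinstance(params, DirichletParams) else DirichletParams()
        scored = [
            (doc_id, score_dirichlet(query, doc_id, index, lm_params))
            for doc_id in sorted(index.docs)
        ]
        scored = [(d, s) for d, s in scored if s > -math.inf]
    else:
        raise ValueError(f"unknown model: {model!r}")
    scored.sort(key=lambda e: (-e[1], e[0]))
    return RunRanking(query.topic_id, scored[:cutoff], cutoff)
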