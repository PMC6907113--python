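"""Sliding-window term-proximity weights (Hyperspace Analogue to Language).

HAL slides a window of size D over a token stream and credits every pair
of occurrences within the window with a strength that decays linearly
with distance: w(l) = D − l + 1, so adjacent terms (l = 1) get D and
terms at the window boundary (l = D) get 1.  The HAL association of a
candidate term t with a query term q in one document is

    HAL(t, q) = Σ_{l=1..D} w(l) · p(t, l, q)

where p(t, l, q) counts co-occurrence pairs at exactly distance l.  The
window here is symmetric — occurrences of t on either side of q count —
because the feedback model only ever consumes the combined count; the
directional row/column view survives in :func:`cooccurrence_matrix`.
All occurrence pairs within D are counted, not just nearest neighbours,
and windows are simply truncated at document boundaries.

The query-level proximity weight multiplies each query term's HAL score
by its IDF, so rare query terms dominate the association:

    W_HAL(t, Q0) = Σ_i HAL(t, q_i) · IDF(q_i)

Instead of one corpus-wide window size, the window may adapt to each
document's length dl (with avg_dl the collection mean):

    f1: D = dl
    f2: D = dl · (1 + dl/avg_dl)
    f3: D = (dl + avg_dl) / (1 + log2(dl/avg_dl))

f3's denominator can go non-positive for very short documents; the
window then falls back to f1 with a logged warning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .corpus import CorpusIndex, TokenizedDocument, idf
from .query import WeightedQuery

__all__ = [
    "WindowSpec",
    "DistanceHistogram",
    "hal_strength",
    "distance_histogram",
    "hal_score",
    "hal_scores_for_doc",
    "w_hal",
    "w_hal_vector",
    "adaptive_window",
    "window_size",
    "cooccurrence_matrix",
]

logger = logging.getLogger(__name__)

ADAPTIVE_VARIANTS = ("f1", "f2", "f3")


@dataclass(frozen=True)
class WindowSpec:
    """Fixed window of size D, or a per-document adaptive window."""

    mode: str = "fixed"
    D: int = 5
    adaptive_variant: str = "f1"

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "adaptive"):
            raise ValueError(f"unknown window mode: {self.mode!r}")
        if self.mode == "fixed" and self.D < 1:
            raise ValueError(f"fixed window needs D >= 1, got {self.D}")
        if self.mode == "adaptive" and self.adaptive_variant not in ADAPTIVE_VARIANTS:
            raise ValueError(f"unknown adaptive variant: {self.adaptive_variant!r}")


@dataclass
class DistanceHistogram:
    """Co-occurrence counts p(t, l, q) for distances l = 1..D."""

    candidate: str
    query_term: str
    D: int
    counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for l, c in self.counts.items():
            if not 1 <= l <= self.D:
                raise ValueError(f"distance {l} outside window 1..{self.D}")
            if c < 0:
                raise ValueError("negative co-occurrence count")


def hal_strength(l: int, D: int) -> int:
    """Distance-decay strength w(l) = D − l + 1 for 1 <= l <= D."""
    if D < 1:
        raise ValueError(f"window size must be >= 1, got {D}")
    if not 1 <= l <= D:
        raise ValueError(f"distance {l} outside window 1..{D}")
    return D - l + 1


def distance_histogram(
    doc: TokenizedDocument, candidate: str, query_term: str, D: int
) -> DistanceHistogram:
    """Count co-occurrences of ``candidate`` around ``query_term``.

    Every (query occurrence i, candidate occurrence j) pair with
    1 <= |i − j| <= D contributes one count at its distance; terms absent
    from the document give an all-zero histogram.
    """
    if D < 1:
        raise ValueError(f"window size must be >= 1, got {D}")
    counts: dict[int, int] = {}
    q_pos = doc.positions(query_term)
    c_pos = doc.positions(candidate)
    for i in q_pos:
        for j in c_pos:
            l = abs(i - j)
            if 1 <= l <= D:
                counts[l] = counts.get(l, 0) + 1
    return DistanceHistogram(candidate, query_term, D, counts)


def hal_score(doc: TokenizedDocument, candidate: str, query_term: str, D: int) -> float:
    """HAL(t, q) = Σ_l w(l) · p(t, l, q) for one document."""
    hist = distance_histogram(doc, candidate, query_term, D)
    return float(sum(hal_strength(l, D) * c for l, c in hist.counts.items()))


def hal_scores_for_doc(
    doc: TokenizedDocument, query_term: str, D: int
) -> dict[str, float]:
    """HAL(t, q) for every term t in the document, in one window sweep.

    Equivalent to calling :func:`hal_score` per candidate but O(occ(q)·D)
    instead of a scan per candidate; used by the expansion engine.
    """
    if D < 1:
        raise ValueError(f"window size must be >= 1, got {D}")
    scores: dict[str, float] = {}
    n = doc.dl
    for i, tok in enumerate(doc.tokens):
        if tok != query_term:
            continue
        lo = max(0, i - D)
        hi = min(n - 1, i + D)
        for j in range(lo, hi + 1):
            if j == i:
                continue
            w = D - abs(i - j) + 1
            t = doc.tokens[j]
            scores[t] = scores.get(t, 0.0) + w
    return scores


def w_hal(
    doc: TokenizedDocument,
    candidate: str,
    original_query: WeightedQuery,
    D: int,
    index: CorpusIndex,
    idf_scheme: str = "bm25",
) -> float:
    """IDF-weighted proximity weight W_HAL(t, Q0) = Σ_i HAL(t, q_i)·IDF(q_i)."""
    if not original_query.weights:
        raise ValueError("empty query")
    total = 0.0
    for q_term in original_query.weights:
        total += hal_score(doc, candidate, q_term, D) * idf(q_term, index, idf_scheme)
    return total


def w_hal_vector(
    doc: TokenizedDocument,
    original_query: WeightedQuery,
    D: int,
    index: CorpusIndex,
    idf_scheme: str = "bm25",
) -> dict[str, float]:
    """W_HAL(t, Q0) for every candidate term t in ``doc`` (single sweep)."""
    if not original_query.weights:
        raise ValueError("empty query")
    out: dict[str, float] = {}
    for q_term in original_query.weights:
        q_idf = idf(q_term, index, idf_scheme)
        if q_idf == 0.0:
            continue
        for term, score in hal_scores_for_doc(doc, q_term, D).items():
            out[term] = out.get(term, 0.0) + score * q_idf
    return out


def adaptive_window(dl: int, avg_dl: float, variant: str = "f1") -> int:
    """Document-length-adaptive window size (variants f1, f2, f3).

    Result is rounded to the nearest integer and floored at 1.
    """
    if dl < 1:
        raise ValueError(f"document length must be >= 1, got {dl}")
    if avg_dl <= 0:
        raise ValueError(f"avg_dl must be positive, got {avg_dl}")
    if variant == "f1":
        value = float(dl)
    elif variant == "f2":
        value = dl * (1.0 + dl / avg_dl)
    elif variant == "f3":
        denom = 1.0 + math.log2(dl / avg_dl)
        if denom <= 0:
            logger.warning(
                "adaptive f3 denominator <= 0 for dl=%d (avg_dl=%.1f); falling back to f1",
                dl,
                avg_dl,
            )
            value = float(dl)
        else:
            value = (dl + avg_dl) / denom
    else:
        raise ValueError(f"unknown adaptive variant: {variant!r}")
    return max(1, round(value))


def window_size(spec: WindowSpec, dl: int, avg_dl: float) -> int:
    """Resolve a WindowSpec to a concrete D for one document."""
    if spec.mode == "fixed":
        return spec.D
    return adaptive_window(dl, avg_dl, spec.adaptive_variant)


def cooccurrence_matrix(doc: TokenizedDocument, D: int) -> pd.DataFrame:
    """Directional HAL matrix for one document (row a, column b).

    Entry (a, b) is the strength-weighted count of occurrences of b
    *preceding* a within the window — the classic row/column semantic
    space view, exposed for debugging and teaching; the feedback model
    itself uses the symmetric counts.
    """
    if D < 1:
        raise ValueError(f"window size must be >= 1, got {D}")
    vocab = sorted(set(doc.tokens))
    mat = pd.DataFrame(0.0, index=vocab, columns=vocab)
    for i, a in enumerate(doc.tokens):
        for j in range(max(0, i - D), i):
            b = doc.tokens[j]
            mat.loc[a, b] += D - (i - j) + 1
    return mat
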