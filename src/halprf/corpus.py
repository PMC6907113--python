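"""Text analysis and inverted-index construction.

The analyzer lowercases, splits on non-alphanumeric characters, optionally
drops stopwords, and Porter-stems each token.  The index keeps positional
postings so that sliding-window proximity counts can be computed for any
(candidate term, query term) pair, plus the collection statistics (N, df,
avg dl, collection frequencies) that BM25 and Dirichlet scoring need.

Token positions are 0-based indices into the post-analysis token stream;
the distance between two occurrences is the absolute position difference,
so adjacent terms are at distance 1.  Stopword removal (off by default)
shortens these distances, which matters for proximity weights.
"""

from __future__ import annotations

import json
import math
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .porter import stem as porter_stem

__all__ = [
    "AnalyzerConfig",
    "TokenizedDocument",
    "Posting",
    "CorpusIndex",
    "tokenize",
    "build_index",
    "idf",
]

_TOKEN_RE = re.compile(r"[0-9a-z]+")


@dataclass(frozen=True)
class AnalyzerConfig:
    """Settings for :func:`tokenize`.

    stopwords are removed *before* stemming; ``ascii_fold`` strips accents
    after NFC normalization.  Defaults keep every token so that proximity
    distances reflect the original text.
    """

    stopwords: frozenset[str] = frozenset()
    stem: bool = True
    ascii_fold: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "stopwords", frozenset(self.stopwords))


DEFAULT_ANALYZER = AnalyzerConfig()


def tokenize(text: str, config: AnalyzerConfig = DEFAULT_ANALYZER) -> list[str]:
    """Normalize ``text`` to an ordered list of stemmed tokens.

    Deterministic for a fixed config; an empty or punctuation-only string
    yields an empty list.
    """
    text = unicodedata.normalize("NFC", text)
    if config.ascii_fold:
        text = unicodedata.normalize("NFKD", text)
        text = "".join(ch for ch in text if not unicodedata.combining(ch))
    tokens = _TOKEN_RE.findall(text.lower())
    if config.stopwords:
        tokens = [t for t in tokens if t not in config.stopwords]
    if config.stem:
        tokens = [porter_stem(t) for t in tokens]
    return tokens


@dataclass
class TokenizedDocument:
    """A document as an ordered token sequence; position = list index."""

    doc_id: str
    tokens: list[str]

    @property
    def dl(self) -> int:
        return len(self.tokens)

    def positions(self, term: str) -> list[int]:
        return [i for i, t in enumerate(self.tokens) if t == term]


@dataclass(frozen=True)
class Posting:
    doc_id: str
    tf: int
    positions: tuple[int, ...]


@dataclass
class CorpusIndex:
    """Inverted index with the collection statistics scoring needs.

    ``postings`` maps term -> list of positional postings (document order
    = insertion order); ``cf`` is the collection frequency used for the
    Dirichlet background model p(w|C) = cf / total_tokens.  Documents are
    retained so feedback documents can be window-scanned without re-reading
    the corpus.
    """

    postings: dict[str, list[Posting]] = field(default_factory=dict)
    docs: dict[str, TokenizedDocument] = field(default_factory=dict)
    n_docs: int = 0
    total_tokens: int = 0

    @property
    def avg_dl(self) -> float:
        return self.total_tokens / self.n_docs if self.n_docs else 0.0

    def df(self, term: str) -> int:
        return len(self.postings.get(term, ()))

    def cf(self, term: str) -> int:
        return sum(p.tf for p in self.postings.get(term, ()))

    def tf(self, term: str, doc_id: str) -> int:
        for p in self.postings.get(term, ()):
            if p.doc_id == doc_id:
                return p.tf
        return 0

    def dl(self, doc_id: str) -> int:
        return self.docs[doc_id].dl

    def p_collection(self, term: str) -> float:
        """Background model p(w|C): collection frequency over total tokens."""
        return self.cf(term) / self.total_tokens if self.total_tokens else 0.0

    @property
    def vocabulary(self) -> Iterator[str]:
        return iter(self.postings)

    # -- persistence ------------------------------------------------------
    FORMAT_VERSION = 1

    def save(self, path: str | Path) -> None:
        """Persist as a versioned JSON layout (round-trip tested)."""
        payload = {
            "format": "halprf-index",
            "version": self.FORMAT_VERSION,
            "docs": {d.doc_id: d.tokens for d in self.docs.values()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "CorpusIndex":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "halprf-index":
            raise ValueError(f"{path}: not a halprf index file")
        if payload.get("version") != cls.FORMAT_VERSION:
            raise ValueError(f"{path}: unsupported index version {payload.get('version')!r}")
        return build_index(
            TokenizedDocument(doc_id, tokens) for doc_id, tokens in payload["docs"].items()
        )


def build_index(docs: Iterable[TokenizedDocument]) -> CorpusIndex:
    """Build a positional inverted index; idempotent for a fixed stream.

    Raises ``ValueError`` naming the offending id on duplicate doc_ids.
    """
    index = CorpusIndex()
    for doc in docs:
        if doc.doc_id in index.docs:
            raise ValueError(f"duplicate doc_id: {doc.doc_id!r}")
        index.docs[doc.doc_id] = doc
        index.n_docs += 1
        index.total_tokens += doc.dl
        occ: dict[str, list[int]] = {}
        for pos, term in enumerate(doc.tokens):
            occ.setdefault(term, []).append(pos)
        for term, positions in occ.items():
            index.postings.setdefault(term, []).append(
                Posting(doc.doc_id, len(positions), tuple(positions))
            )
    return index


def idf(
    term: str,
    index: CorpusIndex | Mapping[str, float],
    scheme: str = "bm25",
    unseen: str = "zero",
) -> float:
    """Inverse document frequency of ``term``.

    ``scheme='bm25'`` gives log((N - df + 0.5) / (df + 0.5)) floored at 0
    (terms in more than half the collection get 0, never a negative);
    ``scheme='plain'`` gives log(N / df).  For df = 0 the ``unseen`` policy
    applies: ``'zero'`` returns 0, ``'max'`` the df=0 value of the formula.
    """
    if isinstance(index, CorpusIndex):
        n, df_t = index.n_docs, index.df(term)
    else:  # mapping interface used by tests: {"N": ..., term: df}
        n, df_t = int(index["N"]), int(index.get(term, 0))
    if df_t == 0 and unseen == "zero":
        return 0.0
    if scheme == "bm25":
        return max(0.0, math.log((n - df_t + 0.5) / (df_t + 0.5)))
    if scheme == "plain":
        if df_t == 0:
            return math.log(n) if n else 0.0
        return math.log(n / df_t)
    raise ValueError(f"unknown idf scheme: {scheme!r}")
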