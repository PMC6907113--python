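"""Deterministic synthetic test collections with planted proximity structure.

Every topic plants five kinds of documents over a shared filler vocabulary:

* *easy relevant* — each query term twice, each designated expansion term
  adjacent to a query term (within the relevant proximity gap);
* *hard relevant* — query terms only once (so the first pass ranks them
  low) but expansion terms several times, again adjacent to query terms;
  these are the documents only a good expansion can recover;
* *near-miss non-relevant* — the same query and expansion terms, but the
  expansion terms at least ``nonrelevant_gap`` tokens away from every
  query occurrence, plus a pair of high-frequency distractor terms far
  from the query terms;
* *distractor-only non-relevant* — the distractor terms alone;
* *background* — pure filler.

The construction makes term proximity, not term frequency, the signal
that separates good expansion terms from distractors: a frequency-only
feedback model is drawn to the distractors (high tf in the near-miss
documents that pollute the feedback set), while sliding-window
co-occurrence scores the distractors at zero.  Placement is
distance-exact, so proximity assertions about the output are
deterministic; all randomness (filler tokens, document lengths, document
order) flows through one seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .evaluation import Qrels
from .trec import Topic, write_qrels, write_topics

__all__ = ["SynthSpec", "SyntheticCollection", "generate_collection"]


@dataclass(frozen=True)
class SynthSpec:
    """Stated world of one synthetic collection.

    ``relevant_gap`` bounds the query-to-expansion-term distance inside
    relevant documents; ``nonrelevant_gap`` is the minimum separation in
    near-miss documents and should exceed any window size under test
    (default 15 = 3x the worked-example window of 5).
    """

    seed: int = 0
    n_docs: int = 500
    n_topics: int = 20
    vocab_size: int = 300  # filler vocabulary, disjoint from planted terms
    doc_len_range: tuple[int, int] = (70, 90)
    relevant_gap: int = 3
    nonrelevant_gap: int = 15
    n_easy_relevant: int = 3
    n_hard_relevant: int = 3
    n_near_miss: int = 4
    n_distractor_docs: int = 2
    distractor_tf: int = 8

    def __post_init__(self) -> None:
        if self.n_docs < 1 or self.n_topics < 1 or self.vocab_size < 1:
            raise ValueError("n_docs, n_topics and vocab_size must be >= 1")
        if self.relevant_gap < 1 or self.nonrelevant_gap < 1:
            raise ValueError("proximity gaps must be positive")
        if self.relevant_gap >= self.nonrelevant_gap:
            raise ValueError("relevant_gap must be smaller than nonrelevant_gap")
        min_len = self.doc_len_range[0]
        if min_len < self.nonrelevant_gap + 20 + self.distractor_tf * 2:
            raise ValueError(
                "documents too short for the requested non-relevant gap layout"
            )
        planted = self.n_topics * self.docs_per_topic
        if planted > self.n_docs:
            raise ValueError(
                f"planted documents ({planted}) exceed n_docs ({self.n_docs})"
            )

    @property
    def docs_per_topic(self) -> int:
        return (
            self.n_easy_relevant
            + self.n_hard_relevant
            + self.n_near_miss
            + self.n_distractor_docs
        )


@dataclass
class SyntheticCollection:
    docs: list[tuple[str, str]]  # (doc_id, raw text)
    topics: list[Topic]
    qrels: Qrels
    query_terms: dict[str, list[str]] = field(default_factory=dict)
    expansion_terms: dict[str, list[str]] = field(default_factory=dict)
    distractor_terms: dict[str, list[str]] = field(default_factory=dict)
    relevant_ids: dict[str, list[str]] = field(default_factory=dict)
    near_miss_ids: dict[str, list[str]] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Emit corpus.jsonl / topics.xml / qrels.txt (the formats trec_io reads)."""
        import json

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "corpus": out / "corpus.jsonl",
            "topics": out / "topics.xml",
            "qrels": out / "qrels.txt",
        }
        paths["corpus"].write_text(
            "".join(
                json.dumps({"id": doc_id, "text": text}) + "\n"
                for doc_id, text in self.docs
            )
        )
        write_topics(self.topics, paths["topics"], "xml")
        write_qrels(self.qrels, paths["qrels"])
        return paths


def _filler_doc(rng: np.random.Generator, length: int, vocab_size: int) -> list[str]:
    return [f"fill{i}" for i in rng.integers(0, vocab_size, size=length)]


def _plant(tokens: list[str], start: int, planted: list[str]) -> None:
    tokens[start : start + len(planted)] = planted


def generate_collection(
    spec: SynthSpec, out_dir: str | Path | None = None
) -> SyntheticCollection:
    """Build a collection per ``spec``; byte-identical for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.doc_len_range

    records: list[tuple[str, list[str], str, int]] = []  # (kind, tokens, topic, grade)
    coll = SyntheticCollection([], [], Qrels())

    for t in range(1, spec.n_topics + 1):
        tid = str(t)
        qa, qb = f"t{t}qa", f"t{t}qb"
        xa, xb = f"t{t}xa", f"t{t}xb"
        da, db = f"t{t}da", f"t{t}db"
        coll.query_terms[tid] = [qa, qb]
        coll.expansion_terms[tid] = [xa, xb]
        coll.distractor_terms[tid] = [da, db]
        coll.topics.append(
            Topic(tid, {"note": f"{qa} {qb}", "description": f"{qa} {qb}"})
        )

        def new_tokens() -> list[str]:
            return _filler_doc(rng, int(rng.integers(lo, hi + 1)), spec.vocab_size)

        # easy relevant: query tf 2, expansion terms adjacent to query terms
        for _ in range(spec.n_easy_relevant):
            toks = new_tokens()
            n = len(toks)
            s1 = int(rng.integers(0, n // 2 - 4))
            s2 = int(rng.integers(n // 2, n - 4))
            _plant(toks, s1, [qa, xa, qb, xb])
            _plant(toks, s2, [qa, xa, qb, xb])
            records.append(("easy", toks, tid, 1))

        # hard relevant: weak query evidence (tf 1), strong expansion evidence
        for _ in range(spec.n_hard_relevant):
            toks = new_tokens()
            n = len(toks)
            s1 = int(rng.integers(0, n - 21))
            _plant(toks, s1, [qa, xa, qb, xb])
            _plant(toks, s1 + 8, [xa, xb])
            _plant(toks, s1 + 16, [xa, xb])
            records.append(("hard", toks, tid, 1))

        # near-miss: same terms, expansion far from every query occurrence,
        # plus high-tf distractors in the tail
        for _ in range(spec.n_near_miss):
            toks = new_tokens()
            n = len(toks)
            b1 = int(rng.integers(0, 4))
            b2 = b1 + 6
            _plant(toks, b1, [qa, qb])
            _plant(toks, b2, [qa, qb])
            x_at = b2 + 1 + spec.nonrelevant_gap + 1
            _plant(toks, x_at, [xa])
            _plant(toks, x_at + 2, [xb])
            tail = list(range(x_at + 4, n))
            slots = rng.choice(tail, size=2 * spec.distractor_tf, replace=False)
            for k, slot in enumerate(sorted(int(s) for s in slots)):
                toks[slot] = da if k % 2 == 0 else db
            records.append(("near_miss", toks, tid, 0))

        # distractor-only: the off-topic documents the distractors drag in
        for _ in range(spec.n_distractor_docs):
            toks = new_tokens()
            slots = rng.choice(
                len(toks), size=2 * spec.distractor_tf, replace=False
            )
            for k, slot in enumerate(sorted(int(s) for s in slots)):
                toks[slot] = da if k % 2 == 0 else db
            records.append(("distractor", toks, tid, 0))

    for _ in range(spec.n_docs - len(records)):
        records.append(
            ("background", _filler_doc(rng, int(rng.integers(lo, hi + 1)), spec.vocab_size), "", 0)
        )

    # shuffle once so document ids carry no class information (ties in
    # first-pass scores then resolve to a seed-dependent feedback mix)
    order = rng.permutation(len(records))
    width = len(str(len(records)))
    for rank, idx in enumerate(order):
        kind, toks, tid, grade = records[idx]
        doc_id = f"d{rank:0{width}d}"
        coll.docs.append((doc_id, " ".join(toks)))
        if tid:
            coll.qrels.add(tid, doc_id, grade)
            if grade > 0:
                coll.relevant_ids.setdefault(tid, []).append(doc_id)
            elif kind == "near_miss":
                coll.near_miss_ids.setdefault(tid, []).append(doc_id)

    if out_dir is not None:
        coll.write(out_dir)
    return coll
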