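"""TREC-style effectiveness metrics, parity 2-fold CV, and grid sweeps.

Average precision follows the trec_eval convention: unjudged documents
count as non-relevant, graded judgments are binarized (relevant iff
grade > 0), and topics with no relevant document are excluded from the
mean with a warning.  F1 is the harmonic mean of precision and recall,
both computed at the same rank cutoff as MAP (1000 by default).
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .retrieval import DEFAULT_CUTOFF, RunRanking

__all__ = [
    "Qrels",
    "MetricReport",
    "average_precision",
    "precision_at_k",
    "recall_at",
    "f1_score",
    "evaluate_run",
    "parity_split",
    "grid_sweep",
    "cross_validate",
    "paired_significance",
]

logger = logging.getLogger(__name__)


@dataclass
class Qrels:
    """Relevance judgments: (topic_id, doc_id) -> integer grade (>0 = relevant)."""

    judgments: dict[tuple[str, str], int] = field(default_factory=dict)

    def add(self, topic_id: str, doc_id: str, grade: int) -> None:
        key = (topic_id, doc_id)
        if key in self.judgments and self.judgments[key] != grade:
            raise ValueError(
                f"conflicting grades for topic {topic_id!r} doc {doc_id!r}"
            )
        self.judgments[key] = grade

    def is_relevant(self, topic_id: str, doc_id: str) -> bool:
        return self.judgments.get((topic_id, doc_id), 0) > 0

    def relevant_docs(self, topic_id: str) -> set[str]:
        return {
            d for (t, d), g in self.judgments.items() if t == topic_id and g > 0
        }

    def topics(self) -> set[str]:
        return {t for t, _ in self.judgments}

    def __len__(self) -> int:
        return len(self.judgments)


@dataclass
class MetricReport:
    """Per-topic metrics plus their arithmetic means."""

    per_topic: pd.DataFrame  # index topic_id; columns ap, p@5, p@10, p@20, recall, f1
    means: pd.Series

    @property
    def map(self) -> float:
        return float(self.means["ap"])


def average_precision(
    ranking: RunRanking, qrels: Qrels, cutoff: int = DEFAULT_CUTOFF
) -> float:
    """AP of one ranked list at ``cutoff``; requires >= 1 relevant document."""
    relevant = qrels.relevant_docs(ranking.topic_id)
    if not relevant:
        raise ValueError(f"topic {ranking.topic_id!r} has no relevant documents")
    hits = 0
    total = 0.0
    for rank, doc_id in enumerate(ranking.doc_ids[:cutoff], start=1):
        if doc_id in relevant:
            hits += 1
            total += hits / rank
    return total / len(relevant)


def precision_at_k(ranking: RunRanking, qrels: Qrels, k: int) -> float:
    """Fraction of the top-k that is relevant; short rankings pad as non-relevant."""
    if k < 1:
        raise ValueError("k must be >= 1")
    top = ranking.doc_ids[:k]
    rel = sum(1 for d in top if qrels.is_relevant(ranking.topic_id, d))
    return rel / k


def recall_at(ranking: RunRanking, qrels: Qrels, cutoff: int = DEFAULT_CUTOFF) -> float:
    relevant = qrels.relevant_docs(ranking.topic_id)
    if not relevant:
        raise ValueError(f"topic {ranking.topic_id!r} has no relevant documents")
    found = sum(1 for d in ranking.doc_ids[:cutoff] if d in relevant)
    return found / len(relevant)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R); 0 when both are 0."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError("precision and recall must be in [0, 1]")
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def evaluate_run(
    rankings: Iterable[RunRanking],
    qrels: Qrels,
    cutoff: int = DEFAULT_CUTOFF,
    p_at: Sequence[int] = (5, 10, 20),
) -> MetricReport:
    """Score a run against qrels, topic by topic.

    Topics without judged-relevant documents are removed (with a warning),
    mirroring the convention of dropping queries without judgments.
    """
    rows: dict[str, dict[str, float]] = {}
    for ranking in rankings:
        if not qrels.relevant_docs(ranking.topic_id):
            logger.warning(
                "topic %s has no relevant judgments; excluded", ranking.topic_id
            )
            continue
        p = precision_at_k(ranking, qrels, cutoff)
        r = recall_at(ranking, qrels, cutoff)
        row = {
            "ap": average_precision(ranking, qrels, cutoff),
            "recall": r,
            "f1": f1_score(p, r),
        }
        for k in p_at:
            row[f"p@{k}"] = precision_at_k(ranking, qrels, k)
        rows[ranking.topic_id] = row
    cols = ["ap"] + [f"p@{k}" for k in p_at] + ["recall", "f1"]
    per_topic = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=cols)
    means = per_topic.mean() if len(per_topic) else pd.Series(0.0, index=cols)
    return MetricReport(per_topic, means)


_NUM_RE = re.compile(r"\d+")


def parity_split(topic_ids: Iterable[str]) -> tuple[list[str], list[str]]:
    """Split topic ids by the parity of their numeric component.

    Returns (even, odd); a topic id with no digits raises, naming the id.
    """
    even: list[str] = []
    odd: list[str] = []
    for tid in topic_ids:
        m = _NUM_RE.search(str(tid))
        if m is None:
            raise ValueError(f"topic id {tid!r} has no numeric component")
        (odd if int(m.group()) % 2 else even).append(tid)
    return even, odd


def grid_sweep(
    train_topics: Sequence[str],
    grid: Mapping[str, Sequence],
    run_fn: Callable[[dict, Sequence[str]], list[RunRanking]],
    qrels: Qrels,
    objective: str = "ap",
    cutoff: int = DEFAULT_CUTOFF,
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive hyper-parameter sweep on the training topics.

    ``run_fn(config, topics)`` produces the rankings for one grid point.
    Returns (best config, full results table); the best point maximizes the
    mean objective, ties broken by first-in-grid order (itertools.product
    over the grid mapping's insertion order).
    """
    names = list(grid)
    points = list(itertools.product(*(grid[n] for n in names)))
    if not points or not names:
        raise ValueError("empty sweep grid")
    records = []
    best: tuple[float, int] | None = None
    for i, values in enumerate(points):
        config = dict(zip(names, values))
        report = evaluate_run(run_fn(config, train_topics), qrels, cutoff)
        score = float(report.means[objective])
        records.append({**config, objective: score})
        if best is None or score > best[0]:
            best = (score, i)
    table = pd.DataFrame.from_records(records)
    best_config = dict(zip(names, points[best[1]]))
    return best_config, table


def cross_validate(
    topic_ids: Sequence[str],
    grid: Mapping[str, Sequence],
    run_fn: Callable[[dict, Sequence[str]], list[RunRanking]],
    qrels: Qrels,
    objective: str = "ap",
    cutoff: int = DEFAULT_CUTOFF,
) -> pd.DataFrame:
    """Parity-based 2-fold cross-validation.

    Hyper-parameters are selected on one fold (by grid sweep) and applied
    once to the held-out fold; rows report the selected config and the
    held-out metrics per fold.
    """
    even, odd = parity_split(topic_ids)
    rows = []
    for train, test, name in ((even, odd, "train-even/test-odd"), (odd, even, "train-odd/test-even")):
        if not train or not test:
            raise ValueError("parity split produced an empty fold")
        best, _ = grid_sweep(train, grid, run_fn, qrels, objective, cutoff)
        report = evaluate_run(run_fn(best, test), qrels, cutoff)
        rows.append({"fold": name, **best, **report.means.to_dict()})
    return pd.DataFrame.from_records(rows)


def paired_significance(
    per_topic_a: pd.Series, per_topic_b: pd.Series
) -> dict[str, float]:
    """Wilcoxon signed-rank and paired-t p-values for two per-topic series.

    Both tests are reported side by side; topics must align by index.
    """
    a, b = per_topic_a.align(per_topic_b, join="inner")
    diffs = a - b
    if (diffs == 0).all():
        wilcoxon_p = 1.0
    else:
        wilcoxon_p = float(stats.wilcoxon(a, b).pvalue)
    ttest_p = float(stats.ttest_rel(a, b).pvalue) if len(a) > 1 else 1.0
    return {"wilcoxon_p": wilcoxon_p, "ttest_p": ttest_p}
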