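"""Sparse weighted query vectors.

Both the original query Q0 (weights = within-query term frequencies) and
every expanded query are the same type, so first-pass and second-pass
retrieval share one scoring path with fractional query-term weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .corpus import AnalyzerConfig, DEFAULT_ANALYZER, tokenize

__all__ = ["WeightedQuery"]


@dataclass
class WeightedQuery:
    topic_id: str
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # zero-weight entries are never retained
        self.weights = {t: float(w) for t, w in self.weights.items() if w != 0.0}

    @classmethod
    def from_text(
        cls,
        topic_id: str,
        text: str,
        config: AnalyzerConfig = DEFAULT_ANALYZER,
    ) -> "WeightedQuery":
        """Analyze ``text``; weights are within-query term frequencies (qtf)."""
        weights: dict[str, float] = {}
        for tok in tokenize(text, config):
            weights[tok] = weights.get(tok, 0.0) + 1.0
        return cls(topic_id, weights)

    @classmethod
    def from_terms(cls, topic_id: str, terms: Iterable[str]) -> "WeightedQuery":
        weights: dict[str, float] = {}
        for t in terms:
            weights[t] = weights.get(t, 0.0) + 1.0
        return cls(topic_id, weights)

    @property
    def terms(self) -> list[str]:
        return list(self.weights)

    def scaled(self, factor: float) -> "WeightedQuery":
        return WeightedQuery(self.topic_id, {t: w * factor for t, w in self.weights.items()})

    def __len__(self) -> int:
        return len(self.weights)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeightedQuery):
            return NotImplemented
        return self.topic_id == other.topic_id and self.weights == other.weights

    def as_dict(self) -> Mapping[str, float]:
        return dict(self.weights)
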