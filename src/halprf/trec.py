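"""Readers and writers for the TREC family of plain-text formats.

Topics (XML in both the ``<topic number=...>`` attribute dialect and the
nested ``<num>`` tag dialect, or JSON-lines), qrels (4-column), runs
(6-column), and corpus ingestion from a directory of ``*.txt`` files or a
JSON-lines file.  All writers are inverses of the corresponding readers
on their own output.
"""

from __future__ import annotations

import json
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .evaluation import Qrels
from .retrieval import RunRanking

__all__ = [
    "Topic",
    "read_topics",
    "write_topics",
    "read_qrels",
    "write_qrels",
    "read_run",
    "write_run",
    "read_corpus",
]

DEFAULT_FIELD_PRIORITY = ("note", "description")


@dataclass
class Topic:
    """One query topic: an id plus named text fields.

    TREC CDS topics carry note/summary/description fields while older
    collections use title/description/narrative; field names are kept
    verbatim and never canonicalized.
    """

    topic_id: str
    fields: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not any(v.strip() for v in self.fields.values()):
            raise ValueError(f"topic {self.topic_id!r} has no non-empty field")

    def query_text(self, prefer: Iterable[str] = DEFAULT_FIELD_PRIORITY) -> str:
        """Text of the field seeding Q0: first preferred name present, else
        the first non-empty field in document order."""
        for name in prefer:
            if self.fields.get(name, "").strip():
                return self.fields[name]
        for value in self.fields.values():
            if value.strip():
                return value
        raise ValueError(f"topic {self.topic_id!r} has no usable field")


def _parse_topic_element(elem: ET.Element) -> Topic:
    topic_id = elem.get("number")
    fields: dict[str, str] = {}
    for child in elem:
        text = (child.text or "").strip()
        if child.tag == "num" and topic_id is None:
            topic_id = re.sub(r"^\s*(Number|Topic)\s*:?\s*", "", text, flags=re.I)
        else:
            fields[child.tag] = text
    if topic_id is None:
        raise ValueError("topic element lacks a number attribute and a <num> tag")
    return Topic(str(topic_id).strip(), fields)


def read_topics(path: str | Path, format: str = "xml") -> list[Topic]:
    """Parse a topic file; duplicate ids and malformed XML raise."""
    path = Path(path)
    topics: list[Topic] = []
    if format == "xml":
        try:
            root = ET.parse(path).getroot()
        except ET.ParseError as exc:  # exc already carries (line, column)
            raise ValueError(f"{path}: malformed XML: {exc}") from exc
        elems = root.iter("topic") if root.tag != "topic" else [root]
        topics = [_parse_topic_element(e) for e in elems]
    elif format == "jsonl":
        for i, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            obj = json.loads(line)
            topics.append(Topic(str(obj["id"]), {k: v for k, v in obj.items() if k != "id"}))
    else:
        raise ValueError(f"unknown topic format: {format!r}")
    seen: set[str] = set()
    for t in topics:
        if t.topic_id in seen:
            raise ValueError(f"duplicate topic_id: {t.topic_id!r}")
        seen.add(t.topic_id)
    return topics


def write_topics(topics: Iterable[Topic], path: str | Path, format: str = "xml") -> None:
    path = Path(path)
    if format == "xml":
        root = ET.Element("topics")
        for t in topics:
            elem = ET.SubElement(root, "topic", number=t.topic_id)
            for name, text in t.fields.items():
                ET.SubElement(elem, name).text = text
        ET.indent(root)
        path.write_text(ET.tostring(root, encoding="unicode") + "\n")
    elif format == "jsonl":
        lines = [json.dumps({"id": t.topic_id, **t.fields}) for t in topics]
        path.write_text("".join(line + "\n" for line in lines))
    else:
        raise ValueError(f"unknown topic format: {format!r}")


def read_qrels(path: str | Path) -> Qrels:
    """Parse 4-column qrels (``topic 0 doc grade``); malformed lines raise
    with their line number, conflicting duplicate judgments raise."""
    qrels = Qrels()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
        topic_id, _, doc_id, grade = parts
        try:
            qrels.add(topic_id, doc_id, int(grade))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return qrels


def write_qrels(qrels: Qrels, path: str | Path) -> None:
    lines = [
        f"{topic} 0 {doc} {grade}"
        for (topic, doc), grade in sorted(qrels.judgments.items())
    ]
    Path(path).write_text("".join(line + "\n" for line in lines))


def write_run(rankings: Iterable[RunRanking], path: str | Path, tag: str = "halprf") -> None:
    """Write standard 6-column TREC run lines, scores at 6 decimals."""
    out = []
    for ranking in rankings:
        for rank, (doc_id, score) in enumerate(ranking.entries, start=1):
            out.append(f"{ranking.topic_id} Q0 {doc_id} {rank} {score:.6f} {tag}")
    Path(path).write_text("".join(line + "\n" for line in out))


def read_run(path: str | Path, cutoff: int = 1000) -> list[RunRanking]:
    per_topic: dict[str, list[tuple[str, float]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6:
            raise ValueError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
        topic_id, _, doc_id, _, score, _ = parts
        per_topic.setdefault(topic_id, []).append((doc_id, float(score)))
    return [RunRanking(t, entries, cutoff) for t, entries in per_topic.items()]


def read_corpus(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (doc_id, raw text) from a ``*.txt`` directory or a JSON-lines file.

    For a directory, doc_id is the filename stem and files are visited in
    sorted order; for JSON-lines, records are ``{"id": ..., "text": ...}``.
    """
    path = Path(path)
    if path.is_dir():
        for f in sorted(path.glob("*.txt")):
            yield f.stem, f.read_text()
    else:
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            obj = json.loads(line)
            yield str(obj["id"]), obj["text"]
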