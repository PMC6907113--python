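"""Independent reference evaluator used only as a test oracle.

Deliberately naive and file-based: it re-parses the *serialized* TREC run
and qrels files line by line and recomputes MAP / P@k / recall with plain
loops, sharing no code with halprf.evaluation (which works on in-memory
objects).  Mirrors trec_eval conventions: documents are ranked by the
score column (ties by doc id), unjudged documents are non-relevant,
grades are binarized at > 0, and topics without relevant documents are
dropped.
"""

from __future__ import annotations

from collections import defaultdict


def _parse_qrels(path):
    rel = defaultdict(set)
    for line in open(path):
        if not line.strip():
            continue
        topic, _, doc, grade = line.split()
        if int(grade) > 0:
            rel[topic].add(doc)
    return rel


def _parse_run(path):
    rows = defaultdict(list)
    for line in open(path):
        if not line.strip():
            continue
        topic, _, doc, _, score, _ = line.split()
        rows[topic].append((doc, float(score)))
    ranked = {}
    for topic, entries in rows.items():
        entries.sort(key=lambda e: (-e[1], e[0]))
        ranked[topic] = [doc for doc, _ in entries]
    return ranked


def reference_metrics(run_path, qrels_path, cutoff=1000, ks=(5, 10, 20)):
    """Per-topic {'ap', 'p@k'..., 'recall'} from the serialized files."""
    rel = _parse_qrels(qrels_path)
    ranked = _parse_run(run_path)
    out = {}
    for topic, docs in ranked.items():
        relevant = rel.get(topic, set())
        if not relevant:
            continue
        hits = 0
        ap_sum = 0.0
        for rank, doc in enumerate(docs[:cutoff], start=1):
            if doc in relevant:
                hits += 1
                ap_sum += hits / rank
        row = {"ap": ap_sum / len(relevant), "recall": hits / len(relevant)}
        for k in ks:
            row[f"p@{k}"] = sum(1 for d in docs[:k] if d in relevant) / k
        out[topic] = row
    return out
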