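"""Benchmark BM25, Rocchio, and the HRoc variants on synthetic collections.

Runs the full index -> first pass -> feedback -> expand -> second pass
pipeline for each model on five seeded collections and prints mean MAP
and P@5, plus a paired significance test of HRoc1 against Rocchio.
MAP near 1.0 means all planted relevant documents (including the
hard-to-retrieve ones) are recovered at the top of the ranking.
"""

import pandas as pd

from halprf import HRocConfig, SynthSpec, WindowSpec, generate_collection, paired_significance
from halprf.pipeline import evaluate, expand_search, index_corpus, search, topics_to_queries

cfg = HRocConfig(alpha=0.5, beta=0.7, n_feedback_docs=5, n_expansion_terms=2,
                 window=WindowSpec("fixed", 5))
models = ["bm25", "rocchio", "hroc1", "hroc2", "hroc3", "hroc_ap1"]
rows = []
per_topic = {"rocchio": [], "hroc1": []}

for seed in range(5):
    coll = generate_collection(SynthSpec(seed=seed, n_docs=500, n_topics=20))
    index = index_corpus(coll.docs)
    queries = topics_to_queries(coll.topics)
    for model in models:
        if model == "bm25":
            runs = search(index, queries)
        else:
            runs = expand_search(index, queries, model, cfg)
        report = evaluate(runs, coll.qrels)
        rows.append({"seed": seed, "model": model, "map": report.map,
                     "p@5": report.means["p@5"], "f1": report.means["f1"]})
        if model in per_topic:
            per_topic[model].append(report.per_topic["ap"].rename(lambda t: f"{seed}:{t}"))

table = pd.DataFrame(rows).groupby("model")[["map", "p@5", "f1"]].mean().loc[models]
print("mean over 5 seeds (20 topics, 500 docs each):")
print(table.to_string(float_format=lambda v: f"{v:.4f}"))

sig = paired_significance(pd.concat(per_topic["hroc1"]), pd.concat(per_topic["rocchio"]))
print(f"\nhroc1 vs rocchio per-topic AP: wilcoxon p={sig['wilcoxon_p']:.2e}, "
      f"paired-t p={sig['ttest_p']:.2e}")
# proximity-aware expansion recovers the weakly-matching relevant documents
# that frequency-only Rocchio loses to the planted distractor terms
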