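"""Proximity-weighted query expansion on a synthetic collection.

Generates a small collection with planted structure, runs the first
pass, and shows the feedback-term table the HRoc engine selects from:
the bm25 column ranks candidates by frequency evidence, the hal column
by sliding-window proximity to the query terms, and 'combined' is the
beta-mix actually used.  Distractor terms score high on frequency but
zero on proximity — exactly the failure mode of frequency-only Rocchio.
"""

from halprf import HRocConfig, SynthSpec, WindowSpec, generate_collection, hroc_expand
from halprf.expansion import feedback_term_table
from halprf.pipeline import index_corpus, search, topics_to_queries
from halprf.retrieval import retrieve

coll = generate_collection(SynthSpec(seed=3, n_docs=120, n_topics=3))
index = index_corpus(coll.docs)
q0 = topics_to_queries(coll.topics)[0]
tid = q0.topic_id
print(f"topic {tid}: query terms {list(q0.weights)}")
print(f"planted expansion terms: {coll.expansion_terms[tid]}")
print(f"planted distractor terms: {coll.distractor_terms[tid]}")

cfg = HRocConfig(alpha=0.5, beta=0.7, n_feedback_docs=5, n_expansion_terms=2,
                 window=WindowSpec("fixed", 5), norm_method="norm1")
first = retrieve(q0, index, "bm25")
feedback = [index.docs[d] for d in first.top(cfg.n_feedback_docs)]

table = feedback_term_table(q0, feedback, cfg, index)
print("\ntop candidate terms (normalized columns in [0,1]):")
print(table.head(6).to_string(float_format=lambda v: f"{v:.3f}"))

q1 = hroc_expand(q0, feedback, cfg, index)
added = {t: round(w, 3) for t, w in q1.weights.items() if t not in q0.weights}
print("\nexpansion terms added to the query:", added)
# the planted txa/txb terms win on the combined score; distractors are excluded
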