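"""Hyper-parameter sweep with parity-based 2-fold cross-validation.

Sweeps the mixing coefficients alpha/beta of HRoc1 on one synthetic
collection: topics are split by the parity of their numbers, the best
grid point is selected on each training fold by MAP, and applied once
to the held-out fold.
"""

from halprf import HRocConfig, SynthSpec, WindowSpec, cross_validate, generate_collection
from halprf.pipeline import expand_search, index_corpus, topics_to_queries

coll = generate_collection(SynthSpec(seed=11, n_docs=300, n_topics=10))
index = index_corpus(coll.docs)
queries = {q.topic_id: q for q in topics_to_queries(coll.topics)}


def run_fn(config, topics):
    cfg = HRocConfig(alpha=config["alpha"], beta=config["beta"],
                     n_feedback_docs=5, n_expansion_terms=2,
                     window=WindowSpec("fixed", 5))
    return expand_search(index, [queries[t] for t in topics], "hroc1", cfg)


grid = {"alpha": [0.3, 0.5], "beta": [0.0, 0.7]}
result = cross_validate(list(queries), grid, run_fn, coll.qrels)
print(result.to_string(float_format=lambda v: f"{v:.4f}", index=False))
# each row: config chosen on the training fold, metrics on the held-out fold;
# beta=0.7 (proximity evidence on) should be selected on both folds
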