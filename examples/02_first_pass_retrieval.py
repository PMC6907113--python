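"""First-pass ranking of a toy corpus with BM25 and the Dirichlet LM.

Indexes six tiny documents and ranks them for one query under both
scoring models; the printed scores are the BM25 sum over query terms and
the query log-likelihood respectively (higher = better in both).
"""

from halprf import DirichletParams, WeightedQuery, retrieve
from halprf.pipeline import index_corpus

corpus = [
    ("pmc1", "Coronary heart disease mortality trends in China."),
    ("pmc2", "Heart transplantation outcomes: a single-centre report."),
    ("pmc3", "Air quality and respiratory disease in Chinese cities."),
    ("pmc4", "Dietary salt, hypertension and heart disease in China."),
    ("pmc5", "Influenza vaccination uptake among the elderly."),
    ("pmc6", "A weather model for daily rainfall reporting."),
]
index = index_corpus(corpus)
print(f"indexed {index.n_docs} docs, avg length {index.avg_dl:.1f} tokens")

query = WeightedQuery.from_text("q1", "heart disease in China")
print("query weights (within-query term frequencies):", query.weights)

for model, params in (("bm25", None), ("dirichlet", DirichletParams(mu=50))):
    run = retrieve(query, index, model, params)
    print(f"\n{model} ranking:")
    for rank, (doc_id, score) in enumerate(run.entries, 1):
        print(f"  {rank}. {doc_id}  score={score:.4f}")
# pmc1/pmc4 match all three content terms and lead under both models
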