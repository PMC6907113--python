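import math

import numpy as np
import pytest

from halprf import (
    BM25Params,
    HRocConfig,
    TokenizedDocument,
    WeightedQuery,
    WindowSpec,
    bm25_feedback_weight,
    build_index,
    feedback_term_table,
    hroc_expand,
    idf,
    normalize,
    retrieve,
    rocchio_expand,
    second_pass,
)
from test_hal import brute_force_hal


class TestNormalize:
    def test_norm1_endpoints(self):
        got = normalize({"a": 1.0, "b": 2.0, "c": 3.0}, "norm1")
        assert got == {"a": 0.0, "b": 0.5, "c": 1.0}

    def test_norm2_three_four_five(self):
        got = normalize({"a": 3.0, "b": 4.0}, "norm2")
        assert got["a"] == pytest.approx(0.6)
        assert got["b"] == pytest.approx(0.8)

    def test_norm3_max_maps_to_one(self):
        assert normalize({"a": 2.0, "b": 4.0}, "norm3") == {"a": 0.5, "b": 1.0}

    def test_degenerate_inputs(self, caplog):
        with caplog.at_level("WARNING"):
            assert normalize({"a": 2.0, "b": 2.0}, "norm1") == {"a": 0.0, "b": 0.0}
        assert any("norm1" in r.message for r in caplog.records)
        assert normalize({"a": 0.0, "b": 0.0}, "norm2") == {"a": 0.0, "b": 0.0}
        assert normalize({"a": 0.0}, "norm3") == {"a": 0.0}
        with pytest.raises(ValueError):
            normalize({}, "norm1")

    def test_contracts_on_random_vectors(self):
        """norm1 in [0,1] with endpoints hit; norm2 unit L2; norm3 max 1."""
        rng = np.random.default_rng(23)
        for _ in range(1000):
            n = int(rng.integers(2, 12))
            scores = {f"t{i}": float(v) for i, v in enumerate(rng.uniform(0, 50, size=n))}
            n1 = normalize(scores, "norm1")
            if max(scores.values()) > min(scores.values()):
                assert all(0.0 <= v <= 1.0 for v in n1.values())
                assert min(n1.values()) == 0.0 and max(n1.values()) == 1.0
            n2 = normalize(scores, "norm2")
            assert math.sqrt(sum(v * v for v in n2.values())) == pytest.approx(1.0)
            n3 = normalize(scores, "norm3")
            assert max(n3.values()) == pytest.approx(1.0)
            for n in (n1, n2, n3):
                assert set(n) == set(scores)


class TestBM25FeedbackWeight:
    def test_absent_term_zero(self, toy_index):
        idx, docs = toy_index
        assert bm25_feedback_weight("zebra", docs[0], idx) == 0.0

    def test_calculator_oracle(self, toy_index):
        idx, docs = toy_index
        p = BM25Params(b=0.5)
        doc = docs[3]  # diseas outbreak report heart diseas (dl 5, tf(diseas)=2)
        k = p.k1 * ((1 - p.b) + p.b * doc.dl / idx.avg_dl)
        expected = (p.k1 + 1) * 2 / (k + 2) * idf("diseas", idx)
        assert bm25_feedback_weight("diseas", doc, idx, p) == pytest.approx(expected)

    def test_saturates_below_k1_plus_one_times_idf(self, toy_index):
        idx, _ = toy_index
        p = BM25Params()
        doc = TokenizedDocument("big", ["china"] * 500)
        cap = (p.k1 + 1) * idf("china", idx)
        w = bm25_feedback_weight("china", doc, idx, p)
        assert 0 < w < cap


class TestRocchioExpand:
    def test_beta_zero_rescales_original_query(self, toy_index):
        idx, docs = toy_index
        q0 = WeightedQuery("t", {"heart": 1.0, "china": 1.0})
        q1 = rocchio_expand(q0, docs[:2], idx, alpha=0.7, beta=0.0)
        assert q1.weights == {t: 0.7 * w for t, w in q0.weights.items()}
        # identical BM25 ranking to the original query
        assert retrieve(q1, idx).doc_ids == retrieve(q0, idx).doc_ids

    def test_alpha_beta_one_single_doc_adds_r(self, toy_index):
        idx, docs = toy_index
        from halprf.expansion import _bm25_doc_vector

        q0 = WeightedQuery("t", {"heart": 1.0})
        r = _bm25_doc_vector(docs[0], idx, BM25Params())
        q1 = rocchio_expand(q0, [docs[0]], idx, alpha=1.0, beta=1.0)
        for term, w in r.items():
            base = q0.weights.get(term, 0.0)
            assert q1.weights[term] == pytest.approx(base + w)

    def test_centroid_is_per_term_mean(self, toy_index):
        idx, docs = toy_index
        from halprf.expansion import _bm25_doc_vector

        q0 = WeightedQuery("t", {"weather": 1.0})
        v1 = _bm25_doc_vector(docs[0], idx, BM25Params())
        v2 = _bm25_doc_vector(docs[1], idx, BM25Params())
        q1 = rocchio_expand(q0, docs[:2], idx, alpha=0.0, beta=1.0)
        for term in set(v1) | set(v2):
            if term == "weather":
                continue
            expected = (v1.get(term, 0.0) + v2.get(term, 0.0)) / 2
            assert q1.weights.get(term, 0.0) == pytest.approx(expected)

    def test_truncation_keeps_top_candidates(self, toy_index):
        idx, docs = toy_index
        q0 = WeightedQuery("t", {"weather": 1.0})
        q1 = rocchio_expand(q0, docs[:3], idx, n_expansion_terms=2)
        assert len([t for t in q1.weights if t != "weather"]) == 2

    def test_empty_feedback_rejected(self, toy_index):
        idx, _ = toy_index
        with pytest.raises(ValueError, match="feedback"):
            rocchio_expand(WeightedQuery("t", {"a": 1.0}), [], idx)


def hroc_oracle(q0, feedback_docs, config, index, params=BM25Params()):
    """Independent end-to-end computation of the expanded query, from the
    component formulas: per-document BM25 vectors and all-pairs HAL counts,
    arithmetic means, normalization, beta-mix, truncation, alpha-merge."""
    n_r = len(feedback_docs)
    mean_bm25, mean_hal = {}, {}
    for doc in feedback_docs:
        k = params.k1 * ((1 - params.b) + params.b * doc.dl / index.avg_dl)
        for term in set(doc.tokens):
            tf = doc.tokens.count(term)
            mean_bm25[term] = mean_bm25.get(term, 0.0) + (
                (params.k1 + 1) * tf / (k + tf) * idf(term, index)
            ) / n_r
            hal = sum(
                brute_force_hal(doc.tokens, term, q, config.window.D) * idf(q, index)
                for q in q0.weights
            )
            mean_hal[term] = mean_hal.get(term, 0.0) + hal / n_r
    cands = sorted(t for t in mean_bm25 if t not in q0.weights)
    bm_n = normalize({t: mean_bm25[t] for t in cands}, config.norm_method)
    hal_n = normalize({t: mean_hal.get(t, 0.0) for t in cands}, config.norm_method)
    combined = {
        t: (1 - config.beta) * bm_n[t] + config.beta * hal_n[t] for t in cands
    }
    chosen = sorted(combined.items(), key=lambda e: (-e[1], e[0]))[: config.n_expansion_terms]
    weights = {t: (1 - config.alpha) * w for t, w in q0.weights.items()}
    for t, w in chosen:
        weights[t] = weights.get(t, 0.0) + config.alpha * w
    return {t: w for t, w in weights.items() if w != 0.0}


class TestHRocExpand:
    def make_collection(self):
        rng = np.random.default_rng(17)
        docs = []
        base = ["alpha", "beta", "gamma", "delta", "eps", "zeta", "eta"]
        for i in range(5):
            tokens = [base[int(j)] for j in rng.integers(0, len(base), size=15)]
            tokens[2], tokens[3] = "qone", "xgood"  # proximity structure
            if i % 2:
                tokens[10] = "qtwo"
            docs.append(TokenizedDocument(f"d{i}", tokens))
        return build_index(docs), docs

    def test_alpha_zero_is_identity(self):
        idx, docs = self.make_collection()
        q0 = WeightedQuery("t", {"qone": 1.0, "qtwo": 2.0})
        cfg = HRocConfig(alpha=0.0, beta=0.5, n_feedback_docs=3, n_expansion_terms=4)
        assert hroc_expand(q0, docs[:3], cfg, idx) == q0

    def test_beta_zero_equals_normalized_rocchio(self):
        idx, docs = self.make_collection()
        q0 = WeightedQuery("t", {"qone": 1.0, "qtwo": 1.0})
        cfg = HRocConfig(alpha=0.6, beta=0.0, n_feedback_docs=3, n_expansion_terms=3,
                         norm_method="norm2")
        via_hroc = hroc_expand(q0, docs[:3], cfg, idx)
        via_rocchio = rocchio_expand(
            q0, docs[:3], idx, alpha=1 - cfg.alpha, beta=cfg.alpha,
            n_expansion_terms=3, norm_method="norm2", include_query_terms=False,
        )
        assert via_hroc.weights == pytest.approx(via_rocchio.weights)

    @pytest.mark.parametrize("norm", ["norm1", "norm2", "norm3"])
    def test_matches_independent_end_to_end_oracle(self, norm):
        idx, docs = self.make_collection()
        q0 = WeightedQuery("t", {"qone": 1.0, "qtwo": 1.0})
        cfg = HRocConfig(alpha=0.4, beta=0.6, n_feedback_docs=5, n_expansion_terms=4,
                         window=WindowSpec("fixed", 3), norm_method=norm)
        got = hroc_expand(q0, docs, cfg, idx)
        assert got.weights == pytest.approx(hroc_oracle(q0, docs, cfg, idx))

    def test_original_terms_survive_expansion(self):
        idx, docs = self.make_collection()
        q0 = WeightedQuery("t", {"qone": 1.0, "qtwo": 1.0})
        for alpha in (0.2, 0.5, 0.9):
            cfg = HRocConfig(alpha=alpha, beta=0.5, n_feedback_docs=4, n_expansion_terms=3)
            q1 = hroc_expand(q0, docs[:4], cfg, idx)
            assert set(q0.weights) <= set(q1.weights)

    def test_all_zero_hal_falls_back_to_bm25_branch(self, caplog):
        # query term absent from every feedback doc -> HAL components all zero
        idx, docs = self.make_collection()
        q0 = WeightedQuery("t", {"nowhere": 1.0})
        cfg = HRocConfig(alpha=0.5, beta=0.9, n_feedback_docs=2, n_expansion_terms=3)
        with caplog.at_level("WARNING"):
            got = hroc_expand(q0, docs[:2], cfg, idx)
        assert any("HAL" in r.message for r in caplog.records)
        expected = hroc_expand(q0, docs[:2],
                               HRocConfig(alpha=0.5, beta=0.0, n_feedback_docs=2,
                                          n_expansion_terms=3), idx)
        assert got.weights == pytest.approx(expected.weights)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            HRocConfig(alpha=1.5)
        with pytest.raises(ValueError):
            HRocConfig(norm_method="norm9")
        with pytest.raises(ValueError):
            HRocConfig(n_feedback_docs=0)

    def test_feedback_term_table_consistent_with_selection(self):
        idx, docs = self.make_collection()
        q0 = WeightedQuery("t", {"qone": 1.0})
        cfg = HRocConfig(alpha=0.5, beta=0.5, n_feedback_docs=5, n_expansion_terms=2)
        table = feedback_term_table(q0, docs, cfg, idx)
        q1 = hroc_expand(q0, docs, cfg, idx)
        expanded = [t for t in q1.weights if t not in q0.weights]
        assert set(expanded) <= set(table.index[: cfg.n_expansion_terms + 2])
        assert (table["combined"].values[:-1] >= table["combined"].values[1:]).all()


class TestSecondPass:
    def test_unexpanded_query_reproduces_first_pass(self, toy_index):
        idx, _ = toy_index
        q0 = WeightedQuery("t", {"heart": 1.0, "diseas": 1.0})
        assert second_pass(q0, idx).entries == retrieve(q0, idx).entries

    def test_zero_weight_term_changes_nothing(self, toy_index):
        idx, _ = toy_index
        q0 = WeightedQuery("t", {"heart": 1.0})
        q_plus = WeightedQuery("t", {"heart": 1.0, "china": 0.0})
        assert second_pass(q_plus, idx).entries == second_pass(q0, idx).entries

    def test_matches_exhaustive_rescore(self, toy_index):
        idx, docs = toy_index
        from halprf import score_bm25

        q = WeightedQuery("t", {"heart": 0.5, "report": 0.25, "china": 1.5})
        run = second_pass(q, idx)
        expected = sorted(
            ((d.doc_id, s) for d in docs if (s := score_bm25(q, d.doc_id, idx)) > 0),
            key=lambda e: (-e[1], e[0]),
        )
        assert run.entries == pytest.approx(expected)
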