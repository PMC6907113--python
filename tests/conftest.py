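import numpy as np
import pytest

from halprf import TokenizedDocument, build_index


@pytest.fixture
def toy_index():
    """Five tiny documents with overlapping vocabulary."""
    docs = [
        TokenizedDocument("d1", ["heart", "diseas", "china", "studi"]),
        TokenizedDocument("d2", ["heart", "attack", "risk", "factor", "studi"]),
        TokenizedDocument("d3", ["china", "popul", "health", "survei"]),
        TokenizedDocument("d4", ["diseas", "outbreak", "report", "heart", "diseas"]),
        TokenizedDocument("d5", ["weather", "report", "daili"]),
    ]
    return build_index(docs), docs


def random_doc(rng: np.random.Generator, length: int, vocab: int) -> TokenizedDocument:
    tokens = [f"w{i}" for i in rng.integers(0, vocab, size=length)]
    return TokenizedDocument(f"doc{rng.integers(0, 10**9)}", tokens)
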