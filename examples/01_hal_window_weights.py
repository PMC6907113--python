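"""Sliding-window proximity weights on a single sentence.

Builds one analyzed document, then shows how the HAL strength decays
with distance and how a candidate term accumulates strength around the
occurrences of a query term.
"""

from halprf import TokenizedDocument, cooccurrence_matrix, distance_histogram, hal_score, hal_strength, tokenize

text = "Aspirin reduces heart attack risk; aspirin also thins the blood."
tokens = tokenize(text)
doc = TokenizedDocument("ex", tokens)
print("analyzed tokens:", tokens)

D = 5
print(f"\nstrength decay for window D={D}:")
for l in range(1, D + 1):
    print(f"  distance {l}: w(l) = {hal_strength(l, D)}")
# adjacent terms get the full window weight 5; at the boundary it is 1

hist = distance_histogram(doc, candidate=tokens[0], query_term=tokens[2], D=D)
print(f"\nco-occurrence histogram for ('{tokens[0]}' near '{tokens[2]}'):", hist.counts)
score = hal_score(doc, tokens[0], tokens[2], D)
print(f"HAL score = sum of strength * count = {score}")
# each count at distance l contributes D - l + 1 to the association

mat = cooccurrence_matrix(doc, D=2)
print("\ndirectional co-occurrence matrix (D=2, rows attend to preceding columns):")
print(mat.to_string(float_format=lambda v: f"{v:.0f}"))
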