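"""Porter's English suffix-stripping stemmer.

Implements the classic five-step algorithm (Porter, 1980) used throughout
text retrieval to conflate morphological variants ("diseases", "disease"
-> "diseas").  Words of length <= 2 are returned unchanged, following the
reference implementation.
"""

from __future__ import annotations

__all__ = ["stem"]


def _is_consonant(word: str, i: int) -> bool:
    ch = word[i]
    if ch in "aeiou":
        return False
    if ch == "y":
        # y is a consonant at word start or after a vowel
        return i == 0 or not _is_consonant(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of vowel-consonant sequences (the m of [C](VC)^m[V])."""
    m = 0
    seen_vowel = False
    for i in range(len(stem)):
        if _is_consonant(stem, i):
            if seen_vowel:
                m += 1
                seen_vowel = False
        else:
            seen_vowel = True
    return m


def _contains_vowel(stem: str) -> bool:
    return any(not _is_consonant(stem, i) for i in range(len(stem)))


def _ends_double_consonant(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_consonant(word, len(word) - 1)
    )


def _ends_cvc(word: str) -> bool:
    # consonant-vowel-consonant where the final consonant is not w, x or y
    if len(word) < 3:
        return False
    return (
        _is_consonant(word, len(word) - 3)
        and not _is_consonant(word, len(word) - 2)
        and _is_consonant(word, len(word) - 1)
        and word[-1] not in "wxy"
    )


# (suffix, replacement) pairs; within a step the longest matching suffix wins
# and, if its m-condition fails, no shorter suffix is tried.
_STEP2 = [
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
]

_STEP3 = [
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
]

_STEP4 = [
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
]


def _longest_match(word: str, suffixes) -> tuple[str, str] | None:
    best = None
    for suf, rep in suffixes:
        if word.endswith(suf) and (best is None or len(suf) > len(best[0])):
            best = (suf, rep)
    return best


def _step1a(w: str) -> str:
    if w.endswith("sses"):
        return w[:-2]
    if w.endswith("ies"):
        return w[:-2]
    if w.endswith("ss"):
        return w
    if w.endswith("s"):
        return w[:-1]
    return w


def _step1b(w: str) -> str:
    if w.endswith("eed"):
        if _measure(w[:-3]) > 0:
            return w[:-1]
        return w
    cleanup = False
    if w.endswith("ed") and _contains_vowel(w[:-2]):
        w = w[:-2]
        cleanup = True
    elif w.endswith("ing") and _contains_vowel(w[:-3]):
        w = w[:-3]
        cleanup = True
    if cleanup:
        if w.endswith(("at", "bl", "iz")):
            return w + "e"
        if _ends_double_consonant(w) and w[-1] not in "lsz":
            return w[:-1]
        if _measure(w) == 1 and _ends_cvc(w):
            return w + "e"
    return w


def _step1c(w: str) -> str:
    if w.endswith("y") and _contains_vowel(w[:-1]):
        return w[:-1] + "i"
    return w


def _step2(w: str) -> str:
    m = _longest_match(w, _STEP2)
    if m is not None:
        suf, rep = m
        stem = w[: -len(suf)]
        if _measure(stem) > 0:
            return stem + rep
    return w


def _step3(w: str) -> str:
    m = _longest_match(w, _STEP3)
    if m is not None:
        suf, rep = m
        stem = w[: -len(suf)]
        if _measure(stem) > 0:
            return stem + rep
    return w


def _step4(w: str) -> str:
    m = _longest_match(w, [(s, "") for s in _STEP4])
    if m is not None:
        suf, _ = m
        stem = w[: -len(suf)]
        if _measure(stem) > 1:
            if suf == "ion" and stem[-1:] not in ("s", "t"):
                return w
            return stem
    return w


def _step5(w: str) -> str:
    if w.endswith("e"):
        stem = w[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _ends_cvc(stem)):
            w = stem
    if w.endswith("ll") and _measure(w[:-1]) > 1:
        w = w[:-1]
    return w


def stem(word: str) -> str:
    """Return the Porter stem of ``word`` (expects lowercase input)."""
    if len(word) <= 2:
        return word
    w = _step1a(word)
    w = _step1b(w)
    w = _step1c(w)
    w = _step2(w)
    w = _step3(w)
    w = _step4(w)
    w = _step5(w)
    return w
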