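"""String-similarity primitives used by the matching cascade.

Two measures are used side by side, on their conventional scales:

* :func:`jaro` — the Jaro similarity on [0, 1];
* :func:`levenshtein_ratio` — a normalised edit similarity on [0, 100],
  computed from the Levenshtein distance with substitution cost 2 (the
  insert/delete metric), so ``ratio = 100 * (1 - dist / (len(a) + len(b)))``.

Convention for degenerate inputs: two equal strings (including two empty
strings) score (1.0, 100.0); an empty string against a non-empty one scores
(0.0, 0.0).
"""

from __future__ import annotations

from functools import lru_cache

__all__ = ["jaro", "levenshtein_ratio", "name_similarity"]


def jaro(a: str, b: str) -> float:
    """Jaro similarity between two strings, on [0, 1]."""
    if a == b:
        return 1.0
    la, lb = len(a), len(b)
    if la == 0 or lb == 0:
        return 0.0
    window = max(la, lb) // 2 - 1
    if window < 0:
        window = 0
    a_flags = [False] * la
    b_flags = [False] * lb
    m = 0
    for i, ca in enumerate(a):
        lo = max(0, i - window)
        hi = min(lb, i + window + 1)
        for j in range(lo, hi):
            if not b_flags[j] and b[j] == ca:
                a_flags[i] = True
                b_flags[j] = True
                m += 1
                break
    if m == 0:
        return 0.0
    # transpositions: matched characters out of order, counted in halves
    t = 0
    j = 0
    for i in range(la):
        if a_flags[i]:
            while not b_flags[j]:
                j += 1
            if a[i] != b[j]:
                t += 1
            j += 1
    t //= 2
    return (m / la + m / lb + (m - t) / m) / 3.0


def levenshtein_ratio(a: str, b: str) -> float:
    """Normalised edit similarity on [0, 100] (substitution cost 2)."""
    if a == b:
        return 100.0
    la, lb = len(a), len(b)
    if la == 0 or lb == 0:
        return 0.0
    # one DP row; dist(a, b) with costs ins=del=1, sub=2
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        ca = a[i - 1]
        for j in range(1, lb + 1):
            sub = prev[j - 1] + (0 if ca == b[j - 1] else 2)
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, sub)
        prev = cur
    dist = prev[lb]
    return 100.0 * (1.0 - dist / (la + lb))


@lru_cache(maxsize=200_000)
def _pair(a: str, b: str) -> tuple[float, float]:
    return jaro(a, b), levenshtein_ratio(a, b)


def name_similarity(a: str, b: str) -> tuple[float, float]:
    """Similarity of two normalized strings on both scales.

    Returns ``(jaro_scale, ratio_scale)`` with jaro on [0, 1] and the
    edit-distance ratio on [0, 100]. Symmetric; memoized, since the cascade
    re-compares the same name pairs across steps.
    """
    if a > b:  # canonical order for the cache
        a, b = b, a
    return _pair(a, b)
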