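"""Independent brute-force oracles, deliberately coded without reference to
the package internals (dict/loop style, exact rational arithmetic)."""

from __future__ import annotations

from fractions import Fraction
from math import comb

WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "U"), ("U", "G")}


def naive_duplex_score(mirna: str, site: str, lo: int = 2, hi: int = 13,
                       double_wobble: bool = True) -> float:
    """Position-by-position penalty sum; miRNA position i (1-based, 5' end)
    pairs with site position len-i+1."""
    assert len(mirna) == len(site)
    L = len(mirna)
    total = Fraction(0)
    for i in range(1, L + 1):
        pair = (mirna[i - 1], site[L - i])
        if pair in WC:
            pen = Fraction(0)
        elif pair in WOBBLE:
            pen = Fraction(1, 2)
        else:
            pen = Fraction(1)
        if lo <= i <= hi and (pair not in WC) and (pair not in WOBBLE or double_wobble):
            pen *= 2
        total += pen
    return float(total)


def naive_scan(mirna: str, transcript: str, max_score: float) -> list[tuple[int, float]]:
    """All (start, score) windows with score <= max_score, sorted by
    (score, start)."""
    L = len(mirna)
    out = []
    for start in range(len(transcript) - L + 1):
        s = naive_duplex_score(mirna, transcript[start:start + L])
        if s <= max_score:
            out.append((start, s))
    out.sort(key=lambda t: (t[1], t[0]))
    return out


def exact_hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by exact rational summation of the hypergeometric pmf."""
    total = Fraction(0)
    denom = comb(N, n)
    for i in range(k, min(K, n) + 1):
        total += Fraction(comb(K, i) * comb(N - K, n - i), denom)
    return float(total)


def bh_step_up(pvals: list[float]) -> list[float]:
    """Textbook Benjamini-Hochberg adjusted p-values."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = pvals[i] * m / rank_from_top
        running_min = min(running_min, val)
        adj[i] = min(running_min, 1.0)
    return adj
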