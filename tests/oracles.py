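"""Independent brute-force oracles, deliberately written with different
algorithms/data structures from the library so each check is a genuine
cross-validation, not a re-run of the same code."""

from __future__ import annotations

import math
from itertools import product


def bleu_bruteforce(candidate, reference, max_n=4):
    """Clipped n-gram precision BLEU via explicit enumeration (no Counter)."""
    if not candidate or not reference:
        return 0.0
    precisions = []
    for n in range(1, max_n + 1):
        cand_grams = [tuple(candidate[i:i + n]) for i in range(len(candidate) - n + 1)]
        ref_grams = [tuple(reference[i:i + n]) for i in range(len(reference) - n + 1)]
        if not cand_grams:
            return 0.0
        clipped = 0
        for g in set(cand_grams):
            clipped += min(cand_grams.count(g), ref_grams.count(g))
        if clipped == 0:
            return 0.0
        precisions.append(clipped / len(cand_grams))
    geo = math.exp(sum(math.log(p) for p in precisions) / max_n)
    c, r = len(candidate), len(reference)
    bp = 1.0 if c >= r else math.exp(1 - r / c)
    return bp * geo


def lcs_recursive(a, b):
    """LCS length via memoized recursion (the library uses iterative DP)."""
    memo = {}

    def rec(i, j):
        if i == len(a) or j == len(b):
            return 0
        if (i, j) not in memo:
            if a[i] == b[j]:
                memo[(i, j)] = 1 + rec(i + 1, j + 1)
            else:
                memo[(i, j)] = max(rec(i + 1, j), rec(i, j + 1))
        return memo[(i, j)]

    return rec(0, 0)


def rouge_l_bruteforce(candidate, reference, beta=1.0):
    if not candidate or not reference:
        return (0.0, 0.0, 0.0)
    lcs = lcs_recursive(list(candidate), list(reference))
    p = lcs / len(candidate)
    r = lcs / len(reference)
    f = 0.0 if p + r == 0 else (1 + beta**2) * p * r / (r + beta**2 * p)
    return (p, r, f)


def kl_direct(p_probs, q_probs):
    """KL divergence from two parallel probability lists."""
    total = 0.0
    for p, q in zip(p_probs, q_probs):
        if p > 0:
            total += p * math.log(p / q)
    return total


def ac1_from_assignments(ratings_per_item, categories):
    """Gwet's AC1 computed from per-item rater-assignment lists.

    ``ratings_per_item``: list of lists, one inner list of chosen categories
    per item. Parametrized by raw assignments rather than count tables, so
    the arithmetic route differs from the library's."""
    q = len(categories)
    items = [r for r in ratings_per_item if len(r) >= 2]
    if not items:
        raise ValueError("no item with >= 2 raters")
    pa_sum = 0.0
    pi_sums = {c: 0.0 for c in categories}
    for ratings in items:
        r_i = len(ratings)
        agree_pairs = 0
        for a in range(r_i):
            for b in range(r_i):
                if a != b and ratings[a] == ratings[b]:
                    agree_pairs += 1
        pa_sum += agree_pairs / (r_i * (r_i - 1))
        for c in categories:
            pi_sums[c] += ratings.count(c) / r_i
    n = len(items)
    pa = pa_sum / n
    pe = sum((s / n) * (1 - s / n) for s in pi_sums.values()) / (q - 1)
    if abs(1 - pe) < 1e-12:
        return math.nan
    return (pa - pe) / (1 - pe)


def greedy_bertscore_nested(cand_vecs, ref_vecs):
    """Per-token max-cosine matching via explicit nested loops."""
    import numpy as np

    def cos(u, v):
        return float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))

    p_terms = []
    for cv in cand_vecs:
        p_terms.append(max(cos(cv, rv) for rv in ref_vecs))
    r_terms = []
    for rv in ref_vecs:
        r_terms.append(max(cos(cv, rv) for cv in cand_vecs))
    p = sum(p_terms) / len(p_terms)
    r = sum(r_terms) / len(r_terms)
    f1 = 0.0 if p + r <= 0 else 2 * p * r / (p + r)
    return p, r, f1


def all_sequences(alphabet, max_len):
    """Every non-empty sequence over ``alphabet`` up to length ``max_len``."""
    for length in range(1, max_len + 1):
        yield from (list(s) for s in product(alphabet, repeat=length))
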