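"""Lexical n-gram overlap metrics: BLEU, ROUGE-L and METEOR.

These are implemented from their original definitions rather than wrapped
from an external scorer, because the exact variant matters for comparability:
BLEU here is the unsmoothed geometric mean of clipped n-gram precisions with
the brevity penalty, ROUGE-L is the LCS-based F measure, and METEOR is the
staged-alignment F-mean with the fragmentation penalty. All three operate on
pre-tokenized, lower-cased sequences; see :func:`scholarprofiler.textutils.tokenize`.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

Tokens = Sequence[str]


@dataclass(frozen=True)
class LexicalScoreSet:
    bleu: float
    rouge_l_precision: float
    rouge_l_recall: float
    rouge_l_f: float
    meteor: float


def _ngrams(tokens: Tokens, n: int) -> Counter:
    return Counter(tuple(tokens[i : i + n]) for i in range(len(tokens) - n + 1))


def bleu(candidate: Tokens, reference: Tokens, max_n: int = 4, smooth: bool = False) -> float:
    """Sentence BLEU: geometric mean of clipped n-gram precisions (n=1..max_n)
    times the brevity penalty exp(1 - r/c) when the candidate is shorter.

    Unsmoothed by default: any zero n-gram precision zeroes the score. With
    ``smooth=True``, zero counts are replaced by 1/(2*denominator)
    (add-epsilon smoothing) so short texts do not collapse to 0.
    """
    if not candidate or not reference:
        logger.warning("BLEU on empty sequence defined as 0")
        return 0.0
    log_precision_sum = 0.0
    for n in range(1, max_n + 1):
        cand_ngrams = _ngrams(candidate, n)
        ref_ngrams = _ngrams(reference, n)
        total = sum(cand_ngrams.values())
        if total == 0:
            if not smooth:
                return 0.0
            clipped, total = 0.5, 1
        else:
            clipped = sum(min(c, ref_ngrams[g]) for g, c in cand_ngrams.items())
            if clipped == 0:
                if not smooth:
                    return 0.0
                clipped = 1.0 / (2.0 * total)
        log_precision_sum += math.log(clipped / total)
    geo_mean = math.exp(log_precision_sum / max_n)
    c, r = len(candidate), len(reference)
    bp = 1.0 if c >= r else math.exp(1.0 - r / c)
    return bp * geo_mean


def _lcs_length(a: Tokens, b: Tokens) -> int:
    # O(len(a)*len(b)) dynamic programme, single rolling row
    prev = [0] * (len(b) + 1)
    for x in a:
        curr = [0]
        for j, y in enumerate(b):
            curr.append(prev[j] + 1 if x == y else max(prev[j + 1], curr[j]))
        prev = curr
    return prev[-1]


def rouge_l(candidate: Tokens, reference: Tokens, beta: float = 1.0) -> tuple[float, float, float]:
    """LCS-based ROUGE: P = LCS/|candidate|, R = LCS/|reference|,
    F = (1+beta^2)PR / (R + beta^2 P)."""
    if not candidate or not reference:
        logger.warning("ROUGE-L on empty sequence defined as (0, 0, 0)")
        return 0.0, 0.0, 0.0
    lcs = _lcs_length(candidate, reference)
    p = lcs / len(candidate)
    r = lcs / len(reference)
    if p == 0.0 and r == 0.0:
        return 0.0, 0.0, 0.0
    f = (1 + beta**2) * p * r / (r + beta**2 * p)
    return p, r, f


def _meteor_alignment(
    candidate: Tokens,
    reference: Tokens,
    stemmer: Callable[[str], str] | None,
    synonyms: Callable[[str], set[str]] | None,
) -> list[tuple[int, int]]:
    """Staged unigram alignment: exact, then stem, then synonym matches on
    the words left unmatched by earlier stages. Within a stage, candidate
    tokens are matched left-to-right to the first available reference token,
    which keeps monotone texts in single chunks."""
    matched: list[tuple[int, int]] = []
    cand_free = [True] * len(candidate)
    ref_free = [True] * len(reference)

    def run_stage(key_c: Callable[[str], object], key_r: Callable[[str], object],
                  match: Callable[[object, object], bool]) -> None:
        for i, ct in enumerate(candidate):
            if not cand_free[i]:
                continue
            for j, rt in enumerate(reference):
                if ref_free[j] and match(key_c(ct), key_r(rt)):
                    matched.append((i, j))
                    cand_free[i] = False
                    ref_free[j] = False
                    break

    run_stage(lambda w: w, lambda w: w, lambda a, b: a == b)
    if stemmer is not None:
        run_stage(stemmer, stemmer, lambda a, b: a == b)
    if synonyms is not None:
        run_stage(lambda w: (w, synonyms(w)), lambda w: w,
                  lambda a, b: b == a[0] or b in a[1])
    return matched


def meteor(
    candidate: Tokens,
    reference: Tokens,
    alpha: float = 0.9,
    beta_pen: float = 3.0,
    gamma: float = 0.5,
    stemmer: Callable[[str], str] | None = None,
    synonyms: Callable[[str], set[str]] | None = None,
) -> float:
    """METEOR: harmonic F-mean PR/(alpha*P + (1-alpha)*R) of unigram
    precision/recall over the staged alignment, discounted by the
    fragmentation penalty gamma*(chunks/matches)^beta_pen.

    A chunk is a maximal run of matches contiguous and in order on both
    sides; fully scrambled matches give chunks == matches.
    """
    if not candidate or not reference:
        logger.warning("METEOR on empty sequence defined as 0")
        return 0.0
    pairs = _meteor_alignment(candidate, reference, stemmer, synonyms)
    m = len(pairs)
    if m == 0:
        return 0.0
    p = m / len(candidate)
    r = m / len(reference)
    f_mean = p * r / (alpha * p + (1 - alpha) * r)
    pairs.sort()
    chunks = 1
    for (ci, ri), (cj, rj) in zip(pairs, pairs[1:]):
        if cj != ci + 1 or rj != ri + 1:
            chunks += 1
    penalty = gamma * (chunks / m) ** beta_pen
    return f_mean * (1.0 - penalty)


def score_pair(candidate: Tokens, reference: Tokens, **meteor_kwargs) -> LexicalScoreSet:
    p, r, f = rouge_l(candidate, reference)
    return LexicalScoreSet(
        bleu=bleu(candidate, reference),
        rouge_l_precision=p,
        rouge_l_recall=r,
        rouge_l_f=f,
        meteor=meteor(candidate, reference, **meteor_kwargs),
    )


def score_pairs(pairs: Sequence[tuple[Tokens, Tokens]]) -> pd.DataFrame:
    """Score each (candidate, reference) pair; the returned frame carries one
    row per pair plus a final ``mean`` row."""
    if not pairs:
        raise ValueError("score_pairs requires at least one pair")
    rows = [score_pair(c, ref).__dict__ for c, ref in pairs]
    df = pd.DataFrame(rows)
    df.loc["mean"] = df.mean()
    return df
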