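"""Chance-corrected inter-rater agreement and paired significance testing.

Gwet's AC1 corrects observed agreement for chance using the category
prevalence estimate pi_q, and unlike Cohen/Fleiss kappa stays stable when
ratings pile up on few categories — exactly the skew seen in Likert-scale
quality ratings. The per-item formulation below handles varying rater counts
(missing ratings) naturally: items rated by fewer than two raters are
dropped and tallied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_LIKERT = ("very poor", "poor", "fair", "good", "excellent")


@dataclass
class RatingTable:
    """Items x categories rating counts: ``counts[item][category]`` is the
    number of raters who chose that category for that item."""

    categories: tuple[Hashable, ...]
    counts: dict[Hashable, dict[Hashable, int]] = field(default_factory=dict)

    @classmethod
    def from_ratings(
        cls,
        ratings: Sequence[tuple[Hashable, Hashable, Hashable]],
        categories: Sequence[Hashable] | None = None,
    ) -> "RatingTable":
        """Build from (item_id, rater_id, category) triples."""
        cats = tuple(categories) if categories is not None else tuple(
            dict.fromkeys(c for _, _, c in ratings)
        )
        counts: dict[Hashable, dict[Hashable, int]] = {}
        for item, _rater, cat in ratings:
            if cat not in cats:
                raise ValueError(f"category {cat!r} not in declared categories")
            counts.setdefault(item, {c: 0 for c in cats})[cat] += 1
        return cls(categories=cats, counts=counts)

    @classmethod
    def from_csv(cls, path, categories: Sequence[Hashable] | None = None) -> "RatingTable":
        """Read an item_id,rater_id,category CSV (a ``dimension`` column, if
        present, is folded into the item id so dimensions pool as items)."""
        df = pd.read_csv(path)
        if "dimension" in df.columns:
            df["item_id"] = df["item_id"].astype(str) + ":" + df["dimension"].astype(str)
        triples = list(df[["item_id", "rater_id", "category"]].itertuples(index=False, name=None))
        return cls.from_ratings(triples, categories)

    def item_ids(self) -> list[Hashable]:
        return list(self.counts)

    def subset(self, items: Sequence[Hashable]) -> "RatingTable":
        return RatingTable(
            categories=self.categories,
            counts={i: dict(self.counts[i]) for i in items if i in self.counts},
        )


def gwet_ac1(t: RatingTable) -> float:
    """Gwet's AC1 for multiple raters with possibly varying rater counts.

    Pa   = mean over items of sum_q r_iq (r_iq - 1) / (r_i (r_i - 1))
    pi_q = mean over items of r_iq / r_i
    Pe   = (1/(Q-1)) * sum_q pi_q (1 - pi_q)
    AC1  = (Pa - Pe) / (1 - Pe)

    Items with fewer than two raters are dropped (with a warning tally);
    raises if none remain or if only one category exists; returns NaN when
    Pe == 1 (degenerate chance agreement).
    """
    q_count = len(t.categories)
    if q_count < 2:
        raise ValueError("AC1 needs at least two rating categories")
    usable = []
    dropped = 0
    for item, cat_counts in t.counts.items():
        r_i = sum(cat_counts.values())
        if r_i < 2:
            dropped += 1
            continue
        usable.append(cat_counts)
    if dropped:
        logger.warning("%d single-rater items dropped from AC1", dropped)
    if not usable:
        raise ValueError("AC1 needs at least one item rated by >= 2 raters")
    pa_terms = []
    pi = {c: 0.0 for c in t.categories}
    for cat_counts in usable:
        r_i = sum(cat_counts.values())
        pa_terms.append(
            sum(r * (r - 1) for r in cat_counts.values()) / (r_i * (r_i - 1))
        )
        for c in t.categories:
            pi[c] += cat_counts.get(c, 0) / r_i
    n = len(usable)
    pa = sum(pa_terms) / n
    pe = sum((p / n) * (1 - p / n) for p in pi.values()) / (q_count - 1)
    if abs(1 - pe) < 1e-12:
        logger.warning("Pe == 1: AC1 undefined for this table")
        return math.nan
    return (pa - pe) / (1 - pe)


def ac1_by_band(
    t: RatingTable, band_of_item: Mapping[Hashable, str]
) -> dict[str, float]:
    """AC1 computed independently per item stratum (e.g. quality band).

    Bands without items — or whose items are all single-rater — report NaN.
    """
    bands: dict[str, list[Hashable]] = {}
    for item in t.item_ids():
        band = band_of_item.get(item)
        if band is not None:
            bands.setdefault(band, []).append(item)
    out: dict[str, float] = {}
    for band, items in bands.items():
        try:
            out[band] = gwet_ac1(t.subset(items))
        except ValueError:
            out[band] = math.nan
    return out


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float
    p_value: float
    significant: bool
    degenerate: bool = False


def paired_t_test(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> PairedTestResult:
    """Two-sided paired t-test on x - y.

    Zero variance of the differences is reported as degenerate (statistic
    and p NaN) rather than raising, since identical score vectors are a
    legitimate pipeline outcome.
    """
    if len(x) != len(y):
        raise ValueError("paired test needs equal-length sequences")
    if len(x) < 2:
        raise ValueError("paired test needs n >= 2")
    diffs = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if np.allclose(diffs.var(ddof=0), 0.0):
        return PairedTestResult(math.nan, math.nan, False, degenerate=True)
    t_stat, p = stats.ttest_rel(x, y)
    return PairedTestResult(float(t_stat), float(p), bool(p < alpha))
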