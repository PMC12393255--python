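"""Topic modeling, dominant-topic assignment, and research-interest stability.

An LDA model fitted over all collected abstracts assigns each publication a
dominant topic; a researcher's diversity score — unique dominant topics over
publication count — separates stable interests (score < 0.3) from shifting
ones (score > 0.7). The backing LDA implementation sits behind a small
contract so any seeded topic model can serve.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from .records import PublicationRecord, ResearcherDossier
from .textutils import content_tokens

logger = logging.getLogger(__name__)

STABLE_THRESHOLD = 0.3
SHIFTING_THRESHOLD = 0.7


class TopicModel(Protocol):
    n_topics: int
    seed: int

    def doc_topic_distribution(self, doc: Sequence[str]) -> np.ndarray: ...


@dataclass
class SklearnLdaModel:
    """Seeded LDA over a fixed bag-of-words vocabulary.

    ``doc_topic_distribution`` returns the variational posterior over topics,
    normalized to sum to 1; identical seed and corpus give identical
    distributions.
    """

    n_topics: int
    seed: int
    vocabulary: dict[str, int]
    _lda: object = None

    def _doc_matrix(self, docs: Sequence[Sequence[str]]) -> np.ndarray:
        x = np.zeros((len(docs), len(self.vocabulary)))
        for i, doc in enumerate(docs):
            for tok in doc:
                j = self.vocabulary.get(tok)
                if j is not None:
                    x[i, j] += 1
        return x

    def doc_topic_distribution(self, doc: Sequence[str]) -> np.ndarray:
        x = self._doc_matrix([doc])
        theta = self._lda.transform(x)[0]
        return theta / theta.sum()


def fit_lda(
    corpus: Sequence[Sequence[str]],
    n_topics: int = 30,
    seed: int = 0,
    max_iter: int = 30,
    n_restarts: int = 1,
) -> SklearnLdaModel:
    """Fit LDA on tokenized, stop-word-filtered abstracts.

    The default of 30 topics suits institution-scale corpora (hundreds of
    researchers); for small corpora a warning fires when there are fewer
    documents than topics. Variational EM is sensitive to initialization on
    small corpora (topics can merge), so ``n_restarts`` fits are run from
    seeds derived from ``seed`` and the one with the best evidence lower
    bound is kept — still fully deterministic given ``seed``.
    """
    from sklearn.decomposition import LatentDirichletAllocation

    if not corpus:
        raise ValueError("cannot fit a topic model on an empty corpus")
    if len(corpus) < n_topics:
        warnings.warn(
            f"corpus of {len(corpus)} documents is smaller than n_topics="
            f"{n_topics}; topic estimates will be unstable",
            stacklevel=2,
        )
    vocab: dict[str, int] = {}
    for doc in corpus:
        for tok in doc:
            vocab.setdefault(tok, len(vocab))
    if not vocab:
        raise ValueError("corpus has an empty vocabulary")
    model = SklearnLdaModel(n_topics=n_topics, seed=seed, vocabulary=vocab)
    x = model._doc_matrix(corpus)
    best, best_bound = None, -np.inf
    for k in range(max(n_restarts, 1)):
        lda = LatentDirichletAllocation(
            n_components=n_topics, random_state=seed + 1000 * k, max_iter=max_iter
        )
        lda.fit(x)
        bound = lda.score(x)
        if bound > best_bound:
            best, best_bound = lda, bound
    model._lda = best
    logger.info(
        "LDA fitted: n_topics=%d seed=%d docs=%d vocab=%d max_iter=%d restarts=%d",
        n_topics, seed, len(corpus), len(vocab), max_iter, n_restarts,
    )
    return model


def dominant_topic(model: TopicModel, doc: Sequence[str]) -> int:
    """Argmax topic of the document's topic distribution; ties break toward
    the lowest index."""
    theta = model.doc_topic_distribution(doc)
    return int(np.argmax(theta))


@dataclass(frozen=True)
class DiversityRecord:
    researcher: str
    n_pubs: int
    n_unique_topics: int
    diversity: float
    band: str
    n_excluded: int = 0


def classify_band(diversity: float) -> str:
    """Strictly below 0.3 is stable, strictly above 0.7 is shifting, the
    boundary values fall in the intermediate band."""
    if diversity < STABLE_THRESHOLD:
        return "stable"
    if diversity > SHIFTING_THRESHOLD:
        return "shifting"
    return "intermediate"


def diversity_score(
    model: TopicModel,
    pubs: Sequence[PublicationRecord],
    researcher: str = "",
    stop_words=None,
) -> DiversityRecord:
    """Unique dominant topics divided by usable publication count.

    Publications without abstracts are excluded from both numerator and
    denominator and tallied in ``n_excluded``.
    """
    usable = [p for p in pubs if p.abstract.strip()]
    n_excluded = len(pubs) - len(usable)
    if not usable:
        raise ValueError("diversity_score needs >= 1 publication with an abstract")
    topics = {
        dominant_topic(model, content_tokens(p.abstract, stop_words)) for p in usable
    }
    diversity = len(topics) / len(usable)
    return DiversityRecord(
        researcher=researcher,
        n_pubs=len(usable),
        n_unique_topics=len(topics),
        diversity=diversity,
        band=classify_band(diversity),
        n_excluded=n_excluded,
    )


def topic_year_table(
    model: TopicModel,
    dossiers: Sequence[ResearcherDossier],
    stop_words=None,
) -> pd.DataFrame:
    """Long-format (researcher, year, topic, count) table of dominant-topic
    assignments — the input for a year-by-year topic heatmap."""
    rows = []
    for d in dossiers:
        for p in d.publications:
            if not p.abstract.strip() or p.pub_year is None:
                continue
            rows.append(
                {
                    "researcher": d.name,
                    "year": p.pub_year,
                    "topic": dominant_topic(model, content_tokens(p.abstract, stop_words)),
                }
            )
    if not rows:
        return pd.DataFrame(columns=["researcher", "year", "topic", "count"])
    df = pd.DataFrame(rows)
    return (
        df.groupby(["researcher", "year", "topic"])
        .size()
        .reset_index(name="count")
        .sort_values(["researcher", "year", "topic"])
        .reset_index(drop=True)
    )
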