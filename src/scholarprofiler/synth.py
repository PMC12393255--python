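"""Seeded synthetic corpora and rating tables with known ground truth.

The generator emulates the statistical structure every metric in this
package assumes, at a desk scale a laptop can evaluate in seconds:

* per-researcher publication sets with planted topic structure — each topic
  owns a vocabulary (optionally sharing a configured fraction of terms with
  the others), abstracts are bag-of-words draws from their topic's
  vocabulary, so LDA can recover the planted partition;
* MeSH headings sampled from per-topic descriptor pools that are present in
  the accompanying synthetic MeSH vocabulary;
* "stable" researchers draw every publication from one topic, "shifting"
  researchers from as many distinct topics as they have publications;
* human-style profiles assembled from the researcher's topic keywords plus
  planted novel MeSH terms that appear in no abstract (ground truth for the
  zero-TF-IDF novelty count);
* multi-rater Likert tables with a controlled copy-the-latent-category
  agreement level for AC1 calibration.

Everything derives from one seed through named substreams, so adding a
component does not shift existing draws. Abstracts are bags of words — no
grammar — which is sufficient for every metric here except the syntactic
suite, whose tests use hand-built parse fixtures instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .agreement import DEFAULT_LIKERT, RatingTable
from .metrics_semantic import MeshVocabulary
from .records import Author, MeshHeading, PublicationRecord, ResearcherDossier


@dataclass
class SynthConfig:
    seed: int = 0
    n_researchers: int = 20
    # inclusive uniform range; kept at or below n_topics so a planted
    # "shifting" researcher (all-distinct topics) really lands above the 0.7
    # diversity threshold
    pubs_per_researcher: tuple[int, int] = (4, 8)
    n_topics: int = 8
    topic_vocab_size: int = 40
    topic_overlap: float = 0.0  # fraction of each topic vocabulary shared
    stable_fraction: float = 0.5
    abstract_length: int = 60  # tokens per abstract
    novel_terms_per_profile: int = 3
    mesh_per_pub: int = 4
    year_range: tuple[int, int] = (2015, 2024)
    n_rating_items: int = 126  # 18 researchers x 7 dimensions
    n_raters: int = 3
    rating_agreement: float = 0.8
    categories: tuple = DEFAULT_LIKERT

    def validate(self) -> None:
        if self.n_researchers < 1 or self.n_topics < 1 or self.topic_vocab_size < 4:
            raise ValueError("counts must be positive (vocab >= 4)")
        for frac in (self.topic_overlap, self.stable_fraction, self.rating_agreement):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction {frac} outside [0, 1]")
        if self.novel_terms_per_profile > self.topic_vocab_size:
            raise ValueError("novel terms exceed the per-topic vocabulary size")


@dataclass
class GroundTruth:
    """Machine-readable sidecar: what was planted, per researcher."""

    topic_of_pub: dict[str, int] = field(default_factory=dict)  # pmid -> topic
    label: dict[str, str] = field(default_factory=dict)  # researcher -> stable|shifting
    novel_terms: dict[str, list[str]] = field(default_factory=dict)
    topics_used: dict[str, list[int]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1)


def hash_name(name: str) -> int:
    # stable across processes (str hash is salted)
    return sum((i + 1) * b for i, b in enumerate(name.encode())) % (2**31)


def _substream(seed: int, name: str) -> np.random.Generator:
    """Named child stream of the global seed; adding a stream never shifts
    the draws of an existing one."""
    return np.random.default_rng([seed, hash_name(name)])


def _topic_vocabularies(cfg: SynthConfig, rng: np.random.Generator) -> list[list[str]]:
    shared_n = int(round(cfg.topic_overlap * cfg.topic_vocab_size))
    shared = [f"shared{j:03d}" for j in range(shared_n)]
    vocabs = []
    for t in range(cfg.n_topics):
        own = [f"topic{t}word{j:03d}" for j in range(cfg.topic_vocab_size - shared_n)]
        vocabs.append(own + shared)
    return vocabs


def make_mesh_vocabulary(cfg: SynthConfig) -> tuple[MeshVocabulary, list[list[str]], list[str]]:
    """Synthetic MeSH vocabulary with per-topic descriptor pools and a
    reserved pool of novelty descriptors that never enter any abstract.

    Tree numbers alternate health (C) and methodology (L) branches so the
    keyword-bucketing step has both kinds to work with.
    """
    vocab = MeshVocabulary()
    topic_pools: list[list[str]] = []
    for t in range(cfg.n_topics):
        pool = []
        for j in range(max(cfg.mesh_per_pub * 2, 6)):
            name = f"Heading T{t} N{j}"
            branch = "C" if j % 2 == 0 else "L"
            vocab.add(name, [f"{branch}{t + 1:02d}.{j:03d}"], [f"entry t{t} n{j}"])
            pool.append(name)
        topic_pools.append(pool)
    novel_pool = []
    for j in range(max(cfg.novel_terms_per_profile * 4, 8)):
        name = f"Novel Concept {j:02d}"
        vocab.add(name, [f"F{90 + j // 10:02d}.{j:03d}"], [])
        novel_pool.append(name)
    return vocab, topic_pools, novel_pool


def make_corpus(cfg: SynthConfig) -> tuple[list[ResearcherDossier], GroundTruth, MeshVocabulary]:
    """Generate dossiers with planted topic structure and ground truth."""
    cfg.validate()
    rng = _substream(cfg.seed, "corpus")
    vocabs = _topic_vocabularies(cfg, rng)
    mesh_vocab, topic_pools, novel_pool = make_mesh_vocabulary(cfg)
    truth = GroundTruth()
    dossiers: list[ResearcherDossier] = []
    n_stable = int(round(cfg.stable_fraction * cfg.n_researchers))
    pmid_counter = 10_000_000
    for r in range(cfg.n_researchers):
        name = f"Ada Scholar{r:03d}"
        stable = r < n_stable
        lo, hi = cfg.pubs_per_researcher
        n_pubs = int(rng.integers(lo, hi + 1))
        if stable:
            topics = [int(rng.integers(cfg.n_topics))] * n_pubs
        else:
            # as many distinct topics as possible, cycling the shuffled list
            order = rng.permutation(cfg.n_topics)
            topics = [int(order[i % cfg.n_topics]) for i in range(n_pubs)]
        pubs = []
        for i, t in enumerate(topics):
            pmid_counter += 1
            pmid = str(pmid_counter)
            words = rng.choice(vocabs[t], size=cfg.abstract_length, replace=True)
            abstract = " ".join(words) + "."
            headings = rng.choice(
                topic_pools[t], size=min(cfg.mesh_per_pub, len(topic_pools[t])),
                replace=False,
            )
            n_coauthors = int(rng.integers(1, 6))
            authors = [Author(f"Coauthor{j}", "B") for j in range(n_coauthors)]
            # place the researcher first, last or middle (60/30/10)
            slot = rng.choice(["first", "last", "middle"], p=[0.6, 0.3, 0.1])
            me = Author("Scholar%03d" % r, "Ada", "Synthetic Institute")
            if slot == "first" or len(authors) < 2:
                authors.insert(0, me)
            elif slot == "last":
                authors.append(me)
            else:
                authors.insert(len(authors) // 2, me)
            year = int(rng.integers(cfg.year_range[0], cfg.year_range[1] + 1))
            pubs.append(
                PublicationRecord(
                    pmid=pmid,
                    title=f"Synthetic study {pmid} on topic {t}",
                    abstract=abstract,
                    authors=tuple(authors),
                    mesh_headings=tuple(MeshHeading(h) for h in headings),
                    pub_year=year,
                )
            )
            truth.topic_of_pub[pmid] = t
        # human profile: topic keywords + planted novel MeSH terms
        profile_topics = sorted(set(topics))
        keyword_sample = [
            w
            for t in profile_topics
            for w in rng.choice(vocabs[t], size=8, replace=False)
        ]
        novel = list(rng.choice(novel_pool, size=cfg.novel_terms_per_profile, replace=False))
        profile = (
            "My research focuses on "
            + ", ".join(keyword_sample)
            + ". Recently I have pioneered "
            + "; ".join(novel)
            + "."
        )
        truth.label[name] = "stable" if stable else "shifting"
        truth.novel_terms[name] = novel
        truth.topics_used[name] = profile_topics
        dossiers.append(
            ResearcherDossier(
                name=name,
                affiliation="Synthetic Institute",
                publications=pubs,
                human_profile=profile,
            )
        )
    return dossiers, truth, mesh_vocab


def make_ratings(cfg: SynthConfig) -> tuple[RatingTable, float]:
    """Likert table with 3 raters per item and controlled agreement.

    Each item has a latent category; a rater copies it with probability
    ``rating_agreement`` and otherwise draws uniformly from the remaining
    categories. Returns the table and the configured agreement level.
    """
    cfg.validate()
    rng = _substream(cfg.seed, "ratings")
    q = len(cfg.categories)
    triples = []
    for i in range(cfg.n_rating_items):
        latent = int(rng.integers(q))
        for r in range(cfg.n_raters):
            if rng.random() < cfg.rating_agreement:
                cat = latent
            else:
                cat = int(rng.integers(q - 1))
                if cat >= latent:
                    cat += 1
            triples.append((f"item{i:04d}", f"rater{r}", cfg.categories[cat]))
    return RatingTable.from_ratings(triples, cfg.categories), cfg.rating_agreement
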