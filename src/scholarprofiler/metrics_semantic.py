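"""Vocabulary-level semantic richness metrics.

The central idea: a profile's informative vocabulary is modelled as a TF-IDF
weight vector, turned into a probability distribution over the union
vocabulary of the compared pair, and the Kullback-Leibler divergence
D_KL(human || machine) quantifies how far the machine profile's vocabulary
fails to cover the human one. Separately, the novelty counter reports
controlled-vocabulary (MeSH) terms that appear in a human-written profile but
in none of the machine profiles — terms the generator never surfaced.

BERTScore lives here too: greedy cosine matching between token embeddings,
precision over candidate tokens and recall over reference tokens, with a
pluggable embedder contract.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Protocol, Sequence

import numpy as np
from lxml import etree

from .textutils import content_tokens, default_stopwords, normalize_term

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# MeSH descriptor vocabulary
# ---------------------------------------------------------------------------


@dataclass
class MeshVocabulary:
    """Descriptor names + entry terms (lower-cased, hyphen/space normalized)
    with their tree numbers; lookups are case-insensitive."""

    descriptors: dict[str, list[str]] = field(default_factory=dict)  # name -> tree numbers
    terms: set[str] = field(default_factory=set)  # normalized names + entry terms
    _term_to_descriptor: dict[str, str] = field(default_factory=dict)

    def __contains__(self, term: str) -> bool:
        return normalize_term(term) in self.terms

    def lookup(self, term: str) -> str | None:
        """Descriptor name for a descriptor/entry term, or None."""
        return self._term_to_descriptor.get(normalize_term(term))

    def tree_numbers(self, descriptor: str) -> list[str]:
        name = self._term_to_descriptor.get(normalize_term(descriptor))
        return self.descriptors.get(name, []) if name else []

    def add(self, name: str, tree_numbers: Iterable[str] = (),
            entry_terms: Iterable[str] = ()) -> None:
        self.descriptors[name] = list(tree_numbers)
        for t in (name, *entry_terms):
            norm = normalize_term(t)
            if norm:
                self.terms.add(norm)
                self._term_to_descriptor.setdefault(norm, name)

    @property
    def max_term_length(self) -> int:
        return max((t.count(" ") + 1 for t in self.terms), default=1)


def load_mesh_vocabulary(source: IO[bytes] | str | bytes) -> MeshVocabulary:
    """Read a MeSH descriptor XML file (the NLM ``desc*.xml`` dialect).

    Captures descriptor names, entry terms (ConceptList/TermList) and tree
    numbers. Raises :class:`ParseError` on malformed XML.
    """
    from .records import ParseError

    try:
        if isinstance(source, (str, bytes)):
            root = etree.fromstring(source.encode() if isinstance(source, str) else source)
        else:
            root = etree.parse(source).getroot()
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed MeSH XML at {exc.position}: {exc}") from exc

    vocab = MeshVocabulary()
    for rec in root.iter("DescriptorRecord"):
        name_node = rec.find("DescriptorName/String")
        if name_node is None or not (name_node.text or "").strip():
            continue
        name = name_node.text.strip()
        trees = [t.text.strip() for t in rec.findall(".//TreeNumberList/TreeNumber") if t.text]
        entries = [
            s.text.strip()
            for s in rec.findall(".//ConceptList/Concept/TermList/Term/String")
            if s.text and s.text.strip()
        ]
        vocab.add(name, trees, entries)
    if not vocab.descriptors:
        logger.warning("MeSH vocabulary is empty")
    return vocab


def serialize_mesh_xml(vocab: MeshVocabulary) -> bytes:
    """Emit a descriptor XML stream in the desc*.xml dialect (used by the
    synthetic generator so fixtures round-trip through the real loader)."""
    root = etree.Element("DescriptorRecordSet")
    for i, (name, trees) in enumerate(sorted(vocab.descriptors.items()), start=1):
        rec = etree.SubElement(root, "DescriptorRecord")
        ui = etree.SubElement(rec, "DescriptorUI")
        ui.text = f"D{i:06d}"
        dn = etree.SubElement(rec, "DescriptorName")
        etree.SubElement(dn, "String").text = name
        if trees:
            tl = etree.SubElement(rec, "TreeNumberList")
            for t in trees:
                etree.SubElement(tl, "TreeNumber").text = t
        entry_terms = [
            t for t, d in vocab._term_to_descriptor.items()
            if d == name and t != normalize_term(name)
        ]
        if entry_terms:
            cl = etree.SubElement(rec, "ConceptList")
            concept = etree.SubElement(cl, "Concept")
            tl = etree.SubElement(concept, "TermList")
            for t in sorted(entry_terms):
                term = etree.SubElement(tl, "Term")
                etree.SubElement(term, "String").text = t
    return etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")


# ---------------------------------------------------------------------------
# TF-IDF vectors and KL divergence
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TermWeightVector:
    doc_id: str
    weights: Mapping[str, float]


@dataclass(frozen=True)
class TermDistribution:
    probabilities: Mapping[str, float]

    def __post_init__(self):
        total = sum(self.probabilities.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {total}, not 1")


def tfidf_weights(
    docs: Sequence[Sequence[str]],
    stop_words: Iterable[str] | None = None,
    doc_ids: Sequence[str] | None = None,
) -> list[TermWeightVector]:
    """Raw-count tf times idf = ln(N/df), stop words removed before counting.

    ``docs`` are tokenized documents; at least two are required because idf
    needs a document-frequency denominator larger than a single document.
    """
    if len(docs) < 2:
        raise ValueError(
            "tfidf_weights needs >= 2 documents: document frequency is "
            "undefined on a single-document corpus"
        )
    sw = default_stopwords() if stop_words is None else frozenset(stop_words)
    filtered = [[t for t in doc if t not in sw] for doc in docs]
    n = len(filtered)
    df: dict[str, int] = {}
    for doc in filtered:
        for term in set(doc):
            df[term] = df.get(term, 0) + 1
    ids = doc_ids if doc_ids is not None else [str(i) for i in range(n)]
    vectors = []
    for doc_id, doc in zip(ids, filtered):
        counts: dict[str, int] = {}
        for t in doc:
            counts[t] = counts.get(t, 0) + 1
        vectors.append(
            TermWeightVector(
                doc_id=doc_id,
                weights={t: c * math.log(n / df[t]) for t, c in counts.items()},
            )
        )
    return vectors


def to_distribution(
    v: TermWeightVector | Mapping[str, float],
    vocabulary: Iterable[str],
    epsilon: float = 1e-9,
) -> TermDistribution:
    """Additive-epsilon smoothing over ``vocabulary`` then renormalization.

    Smoothing keeps the KL divergence finite when a term carries weight in
    one profile and none in the other — the dominant case for the vocabulary
    gap this metric measures.
    """
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    weights = v.weights if isinstance(v, TermWeightVector) else v
    vocab = list(dict.fromkeys(vocabulary))
    if not vocab:
        raise ValueError("empty vocabulary")
    unknown = set(weights) - set(vocab)
    if unknown:
        raise ValueError(f"vector support outside vocabulary: {sorted(unknown)[:5]}")
    raw = {t: weights.get(t, 0.0) + epsilon for t in vocab}
    total = sum(raw.values())
    return TermDistribution({t: w / total for t, w in raw.items()})


def kl_divergence(p: TermDistribution, q: TermDistribution) -> float:
    """D_KL(p || q) = sum_t p(t) ln(p(t)/q(t)), in nats; p(t)=0 terms
    contribute zero. Requires identical supports."""
    if set(p.probabilities) != set(q.probabilities):
        raise ValueError("KL divergence requires identical supports")
    total = 0.0
    for t, pt in p.probabilities.items():
        if pt > 0.0:
            qt = q.probabilities[t]
            if qt <= 0.0:
                return math.inf
            total += pt * math.log(pt / qt)
    return max(total, 0.0)


def profile_kl(
    human: str,
    machine: str,
    corpus: Sequence[str],
    stop_words: Iterable[str] | None = None,
    epsilon: float = 1e-9,
    direction: str = "human_to_machine",
    mode: str = "tfidf",
) -> float | None:
    """Vocabulary-shift divergence for one (human, machine) profile pair.

    The pair's texts are scored with tf-idf against ``corpus`` (the texts are
    appended if absent, so df covers them), each vector is smoothed over the
    union vocabulary of the pair, and D_KL(human || machine) is returned.
    ``direction`` may be ``machine_to_human`` or ``symmetric`` (the mean of
    both); ``mode="tf"`` uses raw term frequencies instead of tf-idf.
    Returns None (with a warning) if either text is empty after stop-word
    removal.
    """
    sw = default_stopwords() if stop_words is None else frozenset(stop_words)
    docs = [content_tokens(t, sw) for t in corpus]
    pair_texts = []
    for text in (human, machine):
        toks = content_tokens(text, sw)
        if text not in corpus:
            docs.append(toks)
        pair_texts.append(toks)
    human_toks, machine_toks = pair_texts
    if not human_toks or not machine_toks:
        logger.warning("profile empty after stop-word removal; KL undefined")
        return None
    if mode == "tf":
        vectors = {
            "h": {t: float(human_toks.count(t)) for t in set(human_toks)},
            "m": {t: float(machine_toks.count(t)) for t in set(machine_toks)},
        }
    elif mode == "tfidf":
        idx_h = docs.index(human_toks)
        idx_m = docs.index(machine_toks)
        tw = tfidf_weights(docs, stop_words=())  # already filtered
        vectors = {"h": dict(tw[idx_h].weights), "m": dict(tw[idx_m].weights)}
    else:
        raise ValueError(f"unknown mode {mode!r}")
    union_vocab = sorted(set(vectors["h"]) | set(vectors["m"]))
    p = to_distribution(vectors["h"], union_vocab, epsilon)
    q = to_distribution(vectors["m"], union_vocab, epsilon)
    if direction == "human_to_machine":
        return kl_divergence(p, q)
    if direction == "machine_to_human":
        return kl_divergence(q, p)
    if direction == "symmetric":
        return 0.5 * (kl_divergence(p, q) + kl_divergence(q, p))
    raise ValueError(f"unknown direction {direction!r}")


def profile_kl_batch(
    pairs: Sequence[tuple[str, str]],
    corpus: Sequence[str] | None = None,
    **kwargs,
) -> tuple[list[float | None], float, float]:
    """KL for each (human, machine) pair plus mean and population variance
    over the defined values. ``corpus`` defaults to all pair texts."""
    if corpus is None:
        corpus = [t for pair in pairs for t in pair]
    values = [profile_kl(h, m, corpus, **kwargs) for h, m in pairs]
    defined = [v for v in values if v is not None]
    if not defined:
        return values, math.nan, math.nan
    mean = float(np.mean(defined))
    var = float(np.var(defined))  # population variance
    return values, mean, var


# ---------------------------------------------------------------------------
# Novel-term count
# ---------------------------------------------------------------------------


def _expand_hyphens(tokens: Sequence[str]) -> list[str]:
    # "natural-language-processing" == "natural language processing" for
    # vocabulary matching purposes
    return [part for t in tokens for part in t.split("-") if part]


def _mesh_phrases(tokens: Sequence[str], vocab: MeshVocabulary) -> list[str]:
    """Longest-match scan: returns the normalized MeSH terms found in the
    token sequence (descriptor names or entry terms, multi-word allowed)."""
    found: list[str] = []
    i = 0
    max_len = vocab.max_term_length
    n = len(tokens)
    while i < n:
        matched = None
        for length in range(min(max_len, n - i), 0, -1):
            phrase = " ".join(tokens[i : i + length])
            if phrase in vocab.terms:
                matched = (phrase, length)
                break
        if matched:
            found.append(matched[0])
            i += matched[1]
        else:
            i += 1
    return found


def novel_term_count(
    human: str,
    machine_texts: Sequence[str],
    stop_words: Iterable[str] | None = None,
    mesh_vocab: MeshVocabulary | None = None,
) -> tuple[int, list[str]]:
    """Count distinct controlled-vocabulary terms that only the human wrote.

    A term is novel when it (a) survives stop-word filtering of the human
    profile, (b) matches a MeSH descriptor or entry term (longest-match
    phrase scan, so multi-word headings count as one concept), and (c) its
    token sequence occurs in none of the machine texts. Without a MeSH
    vocabulary, single filtered tokens absent from every machine text are
    counted instead.
    """
    if not human.strip():
        raise ValueError("novel_term_count requires non-empty human text")
    sw = default_stopwords() if stop_words is None else frozenset(stop_words)
    human_toks = _expand_hyphens(content_tokens(human, sw))
    machine_token_sets = [_expand_hyphens(content_tokens(t, sw)) for t in machine_texts]

    def occurs(phrase: str, toks: Sequence[str]) -> bool:
        words = phrase.split()
        k = len(words)
        return any(list(toks[j : j + k]) == words for j in range(len(toks) - k + 1))

    if mesh_vocab is None:
        candidates = list(dict.fromkeys(human_toks))
    else:
        candidates = list(dict.fromkeys(_mesh_phrases(human_toks, mesh_vocab)))
    novel = [
        term for term in candidates
        if not any(occurs(term, mt) for mt in machine_token_sets)
    ]
    return len(novel), novel


# ---------------------------------------------------------------------------
# BERTScore (greedy embedding matching)
# ---------------------------------------------------------------------------


class TokenEmbedder(Protocol):
    """Maps a token sequence to one fixed-dimension vector per token."""

    def embed(self, tokens: Sequence[str]) -> np.ndarray: ...


class RandomProjectionEmbedder:
    """Deterministic hashing embedder for offline evaluation.

    Each distinct token maps to a fixed random unit vector (seeded by a hash
    of the token and the embedder seed). Context-free: identical tokens get
    identical vectors, so exact lexical matches score cosine 1 and unrelated
    tokens score near 0 in high dimension. This preserves the structure the
    greedy-matching score measures without any model download; a contextual
    transformer can be dropped in through the same contract.
    """

    def __init__(self, dim: int = 64, seed: int = 0):
        self.dim = dim
        self.seed = seed
        self._cache: dict[str, np.ndarray] = {}

    def _vector(self, token: str) -> np.ndarray:
        v = self._cache.get(token)
        if v is None:
            # str hash() is salted per process; use a stable arithmetic key
            key = sum((i + 1) * b for i, b in enumerate(token.encode())) % (2**31)
            rng = np.random.default_rng((self.seed * 1_000_003 + key) % (2**31))
            v = rng.standard_normal(self.dim)
            v /= np.linalg.norm(v)
            self._cache[token] = v
        return v

    def embed(self, tokens: Sequence[str]) -> np.ndarray:
        if not tokens:
            return np.zeros((0, self.dim))
        return np.stack([self._vector(t) for t in tokens])


def bert_score(
    candidate: Sequence[str],
    reference: Sequence[str],
    embedder: TokenEmbedder,
) -> tuple[float, float, float]:
    """Greedy-matching embedding similarity.

    Recall is the mean over reference tokens of the maximum cosine against
    any candidate token; precision is symmetric; F1 is their harmonic mean.
    No idf weighting and no baseline rescaling.
    """
    if not candidate or not reference:
        logger.warning("bert_score on empty sequence defined as (0, 0, 0)")
        return 0.0, 0.0, 0.0
    c = embedder.embed(candidate)
    r = embedder.embed(reference)
    c_norm = c / np.maximum(np.linalg.norm(c, axis=1, keepdims=True), 1e-12)
    r_norm = r / np.maximum(np.linalg.norm(r, axis=1, keepdims=True), 1e-12)
    sim = c_norm @ r_norm.T  # candidate x reference cosine matrix
    precision = float(sim.max(axis=1).mean())
    recall = float(sim.max(axis=0).mean())
    if precision + recall <= 0:
        return precision, recall, 0.0
    f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1
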