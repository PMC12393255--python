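"""Profile generation: MeSH-keyword and abstract-summarization strategies.

Two strategies produce a narrative research-interest profile from a filtered
dossier. The MeSH strategy renders the publications' MeSH keywords, bucketed
into methodology vs. health-domain groups via MeSH tree-branch prefixes, into
a single one-shot prompt. The abstract strategy is divide-and-conquer
map-reduce: publications are grouped by dominant LDA topic, each group is
condensed by one backend call, and a final call combines the per-topic
summaries — so arbitrarily large publication lists fit a bounded context
window. A paraphrase of the human-written profile serves as the evaluation
baseline.

Text generation goes through the :class:`GenerationBackend` contract. The
packaged backends are deterministic (extractive summarizer, echo, identity,
word-shuffle) so the whole stage is reproducible offline; remote-LLM
adapters plug into the same contract.
"""

from __future__ import annotations

import json
import logging
import math
import random
import re
import time
from dataclasses import dataclass, field
from importlib import resources
from typing import Protocol, Sequence

from .records import PublicationRecord, ResearcherDossier
from .textutils import count_tokens, tokenize

logger = logging.getLogger(__name__)

MATERIAL_OPEN = "<<<MATERIAL"
MATERIAL_CLOSE = "MATERIAL>>>"

# MeSH tree branches: E = analytical/diagnostic/therapeutic techniques,
# L = information science, V = publication characteristics; C = diseases,
# F = psychiatry/psychology, G = phenomena and processes.
METHODOLOGY_BRANCHES = ("E", "L", "V")
HEALTH_BRANCHES = ("C", "F", "G")


class GenerationBackend(Protocol):
    context_limit: int
    deterministic: bool

    def generate(self, prompt: str, max_output_tokens: int = 1024) -> str: ...


def extract_material(prompt: str) -> str:
    """The delimited material section of a rendered prompt (the researcher's
    keywords/abstracts), or the whole prompt if no delimiters are present."""
    m = re.search(
        re.escape(MATERIAL_OPEN) + r"\n(.*?)\n" + re.escape(MATERIAL_CLOSE),
        prompt,
        re.DOTALL,
    )
    return m.group(1) if m else prompt


class EchoBackend:
    """Returns the prompt unchanged; for contract tests."""

    context_limit = 1_000_000
    deterministic = True

    def generate(self, prompt: str, max_output_tokens: int = 1024) -> str:
        return prompt


class IdentityBackend:
    """Returns the material section verbatim."""

    context_limit = 1_000_000
    deterministic = True

    def generate(self, prompt: str, max_output_tokens: int = 1024) -> str:
        return extract_material(prompt)


class WordShuffleBackend:
    """Seeded whitespace-token shuffle of the material: a degenerate
    'paraphraser' preserving the token multiset."""

    context_limit = 1_000_000
    deterministic = True

    def __init__(self, seed: int = 0):
        self.seed = seed

    def generate(self, prompt: str, max_output_tokens: int = 1024) -> str:
        words = extract_material(prompt).split()
        random.Random(self.seed).shuffle(words)
        return " ".join(words)


class ExtractiveBackend:
    """Deterministic extractive summarizer: scores each sentence of the
    material by its summed tf-idf weight (sentences as the df corpus) and
    returns the top-k sentences in original order; ties break toward the
    earlier sentence. Keyword lists (no sentence punctuation) are returned
    as-is, truncated to the output budget."""

    context_limit = 128_000  # matches common LLM context windows
    deterministic = True

    def __init__(self, top_k: int = 5):
        self.top_k = top_k

    def generate(self, prompt: str, max_output_tokens: int = 1024) -> str:
        material = extract_material(prompt).strip()
        if not material:
            raise ValueError("empty material section")
        sentences = [s.strip() for s in re.split(r"(?<=[.!?])\s+", material) if s.strip()]
        if len(sentences) <= self.top_k:
            return material
        token_docs = [tokenize(s) for s in sentences]
        n = len(token_docs)
        df: dict[str, int] = {}
        for doc in token_docs:
            for t in set(doc):
                df[t] = df.get(t, 0) + 1
        scores = [
            sum(math.log(n / df[t]) + 1.0 for t in doc) for doc in token_docs
        ]
        ranked = sorted(range(n), key=lambda i: (-scores[i], i))[: self.top_k]
        return " ".join(sentences[i] for i in sorted(ranked))


BACKENDS = {
    "extractive": ExtractiveBackend,
    "echo": EchoBackend,
    "identity": IdentityBackend,
    "shuffle": WordShuffleBackend,
}


# ---------------------------------------------------------------------------
# Prompt templates and provenance
# ---------------------------------------------------------------------------


@dataclass
class PromptTemplate:
    """One-shot prompt skeleton with named slots.

    ``text`` must contain the ``{material}`` slot; ``{example_input}`` /
    ``{example_output}`` hold the single worked example, ``{researcher}``
    the target's name. Rendering with a non-empty example keeps the prompt
    one-shot by construction.
    """

    text: str
    example_input: str = ""
    example_output: str = ""

    @classmethod
    def packaged(cls, name: str, example_input: str = "", example_output: str = "") -> "PromptTemplate":
        text = resources.files("scholarprofiler.templates").joinpath(f"{name}.txt").read_text()
        return cls(text, example_input, example_output)

    def render(self, material: str, researcher: str = "") -> str:
        # plain slot substitution (not str.format): material may contain braces
        out = self.text
        for slot, value in (
            ("{material}", material),
            ("{researcher}", researcher or "the researcher"),
            ("{example_input}", self.example_input or "(none)"),
            ("{example_output}", self.example_output or "(none)"),
        ):
            out = out.replace(slot, value)
        return out


@dataclass
class ProvenanceLog:
    """JSON-lines record of every backend call (prompt, response, stage)."""

    events: list[dict] = field(default_factory=list)

    def record(self, stage: str, prompt: str, response: str) -> None:
        self.events.append(
            {"stage": stage, "prompt": prompt, "response": response, "time": time.time()}
        )

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for e in self.events:
                fh.write(json.dumps(e) + "\n")


def _call(backend: GenerationBackend, prompt: str, stage: str,
          log: ProvenanceLog | None, max_output_tokens: int = 1024) -> str:
    if count_tokens(prompt) > backend.context_limit:
        raise ValueError(
            f"rendered prompt (~{count_tokens(prompt)} tokens) exceeds the "
            f"backend context limit of {backend.context_limit}"
        )
    try:
        out = backend.generate(prompt, max_output_tokens)
    except Exception as exc:
        raise RuntimeError(f"backend failure at stage {stage!r}; prompt was:\n{prompt}") from exc
    if log is not None:
        log.record(stage, prompt, out)
    return out


# ---------------------------------------------------------------------------
# MeSH keyword bucketing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KeywordBuckets:
    methodology_terms: tuple[str, ...]
    health_terms: tuple[str, ...]
    unassigned: tuple[str, ...]


def categorize_mesh(
    terms: Sequence[str],
    mesh_tree: object,
    methodology_branches: Sequence[str] = METHODOLOGY_BRANCHES,
    health_branches: Sequence[str] = HEALTH_BRANCHES,
) -> KeywordBuckets:
    """Partition deduplicated MeSH terms into methodology vs health buckets
    by tree-branch prefix.

    A term all of whose tree numbers sit under the methodology branches is
    methodology; a term with any tree number under a health branch is health
    (a term qualifying for both goes to health — profiles foreground health
    topics); anything else, including terms missing from the tree, is
    unassigned.
    """
    methodology, health, unassigned = [], [], []
    for term in dict.fromkeys(terms):
        trees = (
            mesh_tree.tree_numbers(term)
            if hasattr(mesh_tree, "tree_numbers")
            else mesh_tree.get(term, [])
        )
        if not trees:
            logger.warning("MeSH term %r not in tree; unassigned", term)
            unassigned.append(term)
        elif any(t[:1] in health_branches for t in trees):
            health.append(term)
        elif all(t[:1] in methodology_branches for t in trees):
            methodology.append(term)
        else:
            unassigned.append(term)
    return KeywordBuckets(tuple(methodology), tuple(health), tuple(unassigned))


# ---------------------------------------------------------------------------
# Topic-based chunking for divide-and-conquer summarization
# ---------------------------------------------------------------------------


def chunk_abstracts_by_topic(
    pubs: Sequence[PublicationRecord],
    n_topics: int = 30,
    token_budget: int = 100_000,
    seed: int = 0,
    stop_words=None,
) -> list[list[PublicationRecord]]:
    """Group publications by dominant LDA topic, splitting oversized groups.

    Every publication lands in exactly one group; groups whose combined
    abstracts exceed ``token_budget`` are split greedily in input order. The
    topic count is capped at the number of publications.
    """
    from .textutils import content_tokens
    from .topics import dominant_topic, fit_lda

    usable = [p for p in pubs if p.abstract.strip()]
    if not usable:
        raise ValueError(
            "all abstracts are empty: the abstract-based strategy is "
            "inapplicable; use the MeSH strategy instead"
        )
    oversized = [p for p in usable if count_tokens(p.abstract) > token_budget]
    if oversized:
        raise ValueError(
            f"token_budget={token_budget} is smaller than a single abstract "
            f"(pmid {oversized[0].pmid})"
        )
    if len(usable) == 1:
        return [list(usable)]
    k = min(n_topics, len(usable))
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = fit_lda(
            [content_tokens(p.abstract, stop_words) for p in usable],
            n_topics=k, seed=seed,
        )
    by_topic: dict[int, list[PublicationRecord]] = {}
    for p in usable:
        t = dominant_topic(model, content_tokens(p.abstract, stop_words))
        by_topic.setdefault(t, []).append(p)
    groups: list[list[PublicationRecord]] = []
    for t in sorted(by_topic):
        current: list[PublicationRecord] = []
        budget = 0
        for p in by_topic[t]:
            cost = count_tokens(p.abstract)
            if current and budget + cost > token_budget:
                groups.append(current)
                current, budget = [], 0
            current.append(p)
            budget += cost
        groups.append(current)
    return groups


# ---------------------------------------------------------------------------
# Generation strategies
# ---------------------------------------------------------------------------


def generate_profile_mesh(
    dossier: ResearcherDossier,
    backend: GenerationBackend,
    template: PromptTemplate | None = None,
    mesh_tree: object | None = None,
    log: ProvenanceLog | None = None,
) -> str:
    """MeSH-keyword strategy: one prompt carrying the two keyword buckets
    with the instruction to summarize each domain separately."""
    terms = [m.descriptor for p in dossier.publications for m in p.mesh_headings]
    if not terms:
        raise ValueError(
            f"dossier {dossier.name!r} has no MeSH headings; the MeSH "
            "strategy requires at least one"
        )
    buckets = categorize_mesh(terms, mesh_tree if mesh_tree is not None else {})
    material = (
        "Methodology keywords: "
        + "; ".join(buckets.methodology_terms + buckets.unassigned)
        + "\nHealth-domain keywords: "
        + "; ".join(buckets.health_terms)
    )
    template = template or PromptTemplate.packaged("mesh")
    prompt = template.render(material, dossier.name)
    return _call(backend, prompt, "mesh", log)


def generate_profile_abstract(
    dossier: ResearcherDossier,
    backend: GenerationBackend,
    template: PromptTemplate | None = None,
    final_template: PromptTemplate | None = None,
    n_topics: int = 30,
    token_budget: int = 100_000,
    seed: int = 0,
    log: ProvenanceLog | None = None,
) -> str:
    """Abstract strategy: two-level map-reduce over topic groups.

    k topic groups cost exactly k + 1 backend calls (one per group plus the
    combining call); intermediate summaries are kept in the provenance log.
    """
    groups = chunk_abstracts_by_topic(
        dossier.publications, n_topics=n_topics, token_budget=token_budget, seed=seed
    )
    template = template or PromptTemplate.packaged("abstract_group")
    final_template = final_template or PromptTemplate.packaged("abstract_final")
    summaries = []
    for i, group in enumerate(groups):
        material = "\n\n".join(p.abstract for p in group)
        prompt = template.render(material, dossier.name)
        summaries.append(_call(backend, prompt, f"group_{i}", log))
    final_prompt = final_template.render("\n\n".join(summaries), dossier.name)
    return _call(backend, final_prompt, "final", log)


def paraphrase_profile(
    human_profile: str,
    backend: GenerationBackend,
    template: PromptTemplate | None = None,
    log: ProvenanceLog | None = None,
) -> str:
    """Paraphrase the human-written profile (the evaluation baseline)."""
    if not human_profile.strip():
        raise ValueError("cannot paraphrase an empty profile")
    template = template or PromptTemplate.packaged("paraphrase")
    prompt = template.render(human_profile)
    out = _call(backend, prompt, "paraphrase", log)
    if not out.strip():
        raise RuntimeError("backend returned empty paraphrase")
    return out
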