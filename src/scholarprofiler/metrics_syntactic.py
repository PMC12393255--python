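"""Sentence-structure comparison over dependency parses.

Five measures per document: Universal PoS tag distribution, mean per-sentence
maximum dependency-tree depth, syntactic complexity (mean root-to-token path
length), syntactic ambiguity (mean length of modifier phrases with several
plausible attachment sites), and lexical diversity (distinct words per tag).

Parsing itself is a pluggable contract: any callable that turns text into
:class:`ParsedSentence` values works, and pre-parsed CoNLL-U input is
accepted directly, so the measures are testable without any model download.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

# Dependency labels whose subtree is a candidate attachment-ambiguous
# modifier phrase: adpositional/oblique nominal modifiers and
# relative/participial/adverbial clauses.
MODIFIER_LABELS = ("nmod", "obl", "acl", "advcl")

# PoS tags that can plausibly govern such a modifier.
ATTACHMENT_HEAD_TAGS = frozenset({"NOUN", "PROPN", "VERB"})


@dataclass(frozen=True)
class ParsedToken:
    form: str
    upos: str
    head: int  # index into the sentence; the root token heads itself
    deprel: str = "dep"


@dataclass(frozen=True)
class ParsedSentence:
    """A dependency tree: exactly one token has head == its own index."""

    tokens: tuple[ParsedToken, ...]

    def __post_init__(self):
        n = len(self.tokens)
        roots = [i for i, t in enumerate(self.tokens) if t.head == i]
        if n and len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        for t in self.tokens:
            if not (0 <= t.head < n):
                raise ValueError(f"head index {t.head} out of range")

    @property
    def root(self) -> int:
        return next(i for i, t in enumerate(self.tokens) if t.head == i)

    def depths(self) -> list[int]:
        """Edges from root to each token; raises on a cyclic head graph."""
        n = len(self.tokens)
        depths = [-1] * n
        for i in range(n):
            if depths[i] >= 0:
                continue
            path: list[int] = []
            j = i
            # walk up head links until hitting the root or a solved token
            while depths[j] < 0 and self.tokens[j].head != j:
                if j in path:
                    raise ValueError("cyclic head graph")
                path.append(j)
                j = self.tokens[j].head
            if self.tokens[j].head == j:
                depths[j] = 0
            base = depths[j]
            for k in reversed(path):
                base += 1
                depths[k] = base
        return depths

    def children(self) -> dict[int, list[int]]:
        ch: dict[int, list[int]] = defaultdict(list)
        for i, t in enumerate(self.tokens):
            if t.head != i:
                ch[t.head].append(i)
        return ch

    def subtree(self, idx: int) -> list[int]:
        ch = self.children()
        out, stack = [], [idx]
        while stack:
            j = stack.pop()
            out.append(j)
            stack.extend(ch.get(j, ()))
        return sorted(out)


@dataclass
class SyntacticProfile:
    pos_distribution: dict[str, float]
    max_dep_depth: float
    syntactic_complexity: float
    syntactic_ambiguity: float
    lexical_diversity: dict[str, int]
    n_sentences: int = 0
    n_skipped: int = 0


def dependency_depth(s: ParsedSentence) -> int:
    """Maximum number of edges from the root to any token (root depth 0)."""
    if not s.tokens:
        return 0
    return max(s.depths())


def syntactic_complexity(s: ParsedSentence) -> float:
    """Mean root-to-token path length (edges) over non-root tokens; 0 for a
    single-token sentence."""
    if len(s.tokens) <= 1:
        return 0.0
    d = s.depths()
    non_root = [d[i] for i in range(len(s.tokens)) if i != s.root]
    return sum(non_root) / len(non_root)


def ambiguous_spans(s: ParsedSentence) -> list[list[int]]:
    """Maximal modifier-phrase subtrees with >= 2 plausible attachment heads
    earlier in the sentence.

    A candidate span is the subtree of a token whose dependency label starts
    with one of :data:`MODIFIER_LABELS` (covers subtypes like ``acl:relcl``);
    nested candidates are absorbed into the outermost one. The span counts
    as ambiguous when at least two noun/proper-noun/verb tokens precede its
    first token — each a syntactically plausible attachment site.
    """
    candidates = [
        i for i, t in enumerate(s.tokens)
        if t.head != i and any(t.deprel.startswith(lbl) for lbl in MODIFIER_LABELS)
    ]
    spans: list[list[int]] = []
    covered: set[int] = set()
    # outermost first: sort by subtree size descending
    for i in sorted(candidates, key=lambda i: -len(s.subtree(i))):
        if i in covered:
            continue
        span = s.subtree(i)
        covered.update(span)
        start = min(span)
        heads_before = sum(
            1 for j in range(start) if s.tokens[j].upos in ATTACHMENT_HEAD_TAGS
        )
        if heads_before >= 2:
            spans.append(span)
    return spans


def syntactic_ambiguity(s: ParsedSentence) -> float:
    """Mean token length of attachment-ambiguous modifier phrases; 0 if the
    sentence has none."""
    spans = ambiguous_spans(s)
    if not spans:
        return 0.0
    return sum(len(sp) for sp in spans) / len(spans)


def pos_distribution(sentences: Sequence[ParsedSentence]) -> dict[str, float]:
    """Per-tag token percentage over all sentences (sums to 100)."""
    counts: dict[str, int] = defaultdict(int)
    total = 0
    for s in sentences:
        for t in s.tokens:
            counts[t.upos] += 1
            total += 1
    if total == 0:
        raise ValueError("pos_distribution requires at least one token")
    return {tag: 100.0 * c / total for tag, c in sorted(counts.items())}


def lexical_diversity(sentences: Sequence[ParsedSentence]) -> dict[str, int]:
    """Distinct lower-cased surface forms per PoS tag."""
    forms: dict[str, set[str]] = defaultdict(set)
    for s in sentences:
        for t in s.tokens:
            forms[t.upos].add(t.form.lower())
    return {tag: len(v) for tag, v in sorted(forms.items())}


Parser = Callable[[str], Iterable[ParsedSentence]]


def syntactic_profile(text: str, parser: Parser) -> SyntacticProfile:
    """Aggregate the five measures over all sentences of a document.

    Scalar measures are means over sentences; a sentence the parser fails on
    is skipped with a warning and counted in ``n_skipped``.
    """
    sentences: list[ParsedSentence] = []
    skipped = 0
    for s in parser(text):
        try:
            if isinstance(s, ParsedSentence) and s.tokens:
                s.depths()  # validates tree structure
                sentences.append(s)
            else:
                skipped += 1
        except ValueError as exc:
            logger.warning("sentence skipped: %s", exc)
            skipped += 1
    if not sentences:
        raise ValueError("no parseable sentences in document")
    return SyntacticProfile(
        pos_distribution=pos_distribution(sentences),
        max_dep_depth=sum(dependency_depth(s) for s in sentences) / len(sentences),
        syntactic_complexity=sum(syntactic_complexity(s) for s in sentences) / len(sentences),
        syntactic_ambiguity=sum(syntactic_ambiguity(s) for s in sentences) / len(sentences),
        lexical_diversity=lexical_diversity(sentences),
        n_sentences=len(sentences),
        n_skipped=skipped,
    )


# ---------------------------------------------------------------------------
# CoNLL-U input
# ---------------------------------------------------------------------------


def parse_conllu(text: str) -> list[ParsedSentence]:
    """Read CoNLL-U formatted parses (columns ID FORM LEMMA UPOS ... HEAD
    DEPREL ...). CoNLL-U's head=0 root convention is converted to the
    self-headed convention used here; multiword ranges and empty nodes are
    ignored."""
    sentences: list[ParsedSentence] = []
    current: list[tuple[str, str, int, str]] = []

    def flush():
        if not current:
            return
        tokens = tuple(
            ParsedToken(form, upos, (head - 1) if head > 0 else i, deprel)
            for i, (form, upos, head, deprel) in enumerate(current)
        )
        sentences.append(ParsedSentence(tokens))
        current.clear()

    for line in text.splitlines():
        line = line.strip()
        if not line:
            flush()
            continue
        if line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 8 or not cols[0].isdigit():
            continue  # multiword token ranges (1-2) and empty nodes (1.1)
        current.append((cols[1], cols[3], int(cols[6]), cols[7]))
    flush()
    return sentences
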