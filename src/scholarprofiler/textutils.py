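"""Shared tokenization and stop-word handling.

Every metric in the package operates on the same token stream: lower-cased,
punctuation-stripped whitespace tokens. Keeping the tokenizer in one place
means the TF-IDF vocabulary, the lexical metrics and the novelty counter all
see identical tokens for identical text.
"""

from __future__ import annotations

import re
from functools import lru_cache
from importlib import resources
from typing import Iterable

_TOKEN_RE = re.compile(r"[a-z0-9]+(?:[-'][a-z0-9]+)*")


def tokenize(text: str) -> list[str]:
    """Lower-cased word tokens; internal hyphens/apostrophes kept, other
    punctuation discarded."""
    return _TOKEN_RE.findall(text.lower())


def normalize_term(term: str) -> str:
    """Canonical form for vocabulary matching: lower-case, hyphens treated as
    spaces, runs of whitespace collapsed."""
    return " ".join(tokenize(term.replace("-", " ")))


@lru_cache(maxsize=1)
def default_stopwords() -> frozenset[str]:
    """The packaged stop-word list (one token per line, '#' comments)."""
    text = resources.files("scholarprofiler.data").joinpath("stopwords.txt").read_text()
    return frozenset(
        line.strip().lower()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


def load_stopwords(path) -> frozenset[str]:
    with open(path, encoding="utf-8") as fh:
        return frozenset(
            line.strip().lower()
            for line in fh
            if line.strip() and not line.startswith("#")
        )


def content_tokens(text: str, stop_words: Iterable[str] | None = None) -> list[str]:
    """Tokens with stop words removed; order preserved."""
    sw = default_stopwords() if stop_words is None else frozenset(stop_words)
    return [t for t in tokenize(text) if t not in sw]


def count_tokens(text: str, inflation: float = 1.3) -> int:
    """Approximate LLM token count: whitespace tokens times an inflation
    factor (subword tokenizers emit ~1.3 pieces per word for English)."""
    return int(len(text.split()) * inflation) + 1
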