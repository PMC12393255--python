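"""Pipeline orchestration and the consolidated evaluation report.

``run_pipeline`` drives the full flow — filter dossiers, generate profiles
with both strategies plus the paraphrase baseline, and score every enabled
metric family per researcher — and returns a bundle of per-researcher rows,
per-system means, paired-test annotations and full provenance. Researchers
without a human-written profile are excluded from reference-based metrics
but still receive generated profiles, each exclusion tallied.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import generation, metrics_lexical, metrics_semantic
from .agreement import paired_t_test
from .records import ResearcherDossier, filter_publications
from .textutils import tokenize

logger = logging.getLogger(__name__)


def significance_legend(p: float) -> str:
    """Figure-style significance bucket: ns, *, ** or ***."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p >= 0.05:
        return "ns"
    if p >= 0.01:
        return "*"
    if p >= 0.001:
        return "**"
    return "***"


@dataclass
class RunConfig:
    seed: int = 0
    reference_year: int = 2024
    window_years: int = 10
    author_rule: str = "first3last3"
    apply_filter: bool = True
    n_topics: int = 8
    token_budget: int = 100_000
    epsilon: float = 1e-9
    alpha: float = 0.05
    backend: str = "extractive"
    kl_direction: str = "human_to_machine"
    kl_mode: str = "tfidf"
    embed_dim: int = 64
    strategies: tuple[str, ...] = ("mesh", "abstract", "paraphrase")

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        d["strategies"] = tuple(d.get("strategies", ("mesh", "abstract", "paraphrase")))
        return cls(**d)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class ReportBundle:
    config: RunConfig
    profiles: dict[str, dict[str, str]]  # researcher -> {system: text}
    rows: pd.DataFrame
    means: pd.DataFrame
    tests: pd.DataFrame
    exclusions: dict[str, int] = field(default_factory=dict)

    def write(self, outdir) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        self.config.to_json(os.path.join(outdir, "config.json"))
        self.rows.to_csv(os.path.join(outdir, "per_researcher.csv"), index=False)
        self.means.to_csv(os.path.join(outdir, "system_means.csv"))
        self.tests.to_csv(os.path.join(outdir, "paired_tests.csv"), index=False)
        with open(os.path.join(outdir, "profiles.json"), "w", encoding="utf-8") as fh:
            json.dump(self.profiles, fh, indent=1, sort_keys=True)
        with open(os.path.join(outdir, "exclusions.json"), "w", encoding="utf-8") as fh:
            json.dump(self.exclusions, fh, indent=1, sort_keys=True)


def run_pipeline(
    dossiers: list[ResearcherDossier],
    cfg: RunConfig,
    mesh_vocab=None,
) -> ReportBundle:
    """Generate profiles for every dossier and evaluate those with a human
    reference. Deterministic given (dossiers, cfg) and a deterministic
    backend."""
    backend = generation.BACKENDS[cfg.backend]()
    embedder = metrics_semantic.RandomProjectionEmbedder(dim=cfg.embed_dim, seed=cfg.seed)
    exclusions = {"no_publications_after_filter": 0, "no_human_profile": 0}

    profiles: dict[str, dict[str, str]] = {}
    for d in dossiers:
        fd = (
            filter_publications(
                d, cfg.reference_year, cfg.window_years, cfg.author_rule
            )
            if cfg.apply_filter
            else d
        )
        if not fd.publications:
            exclusions["no_publications_after_filter"] += 1
            logger.info("event=excluded researcher=%r reason=no_publications", d.name)
            continue
        systems: dict[str, str] = {}
        if "mesh" in cfg.strategies:
            try:
                systems["mesh"] = generation.generate_profile_mesh(
                    fd, backend, mesh_tree=mesh_vocab
                )
            except ValueError as exc:
                logger.warning("mesh strategy skipped for %r: %s", d.name, exc)
        if "abstract" in cfg.strategies:
            try:
                systems["abstract"] = generation.generate_profile_abstract(
                    fd, backend, n_topics=cfg.n_topics,
                    token_budget=cfg.token_budget, seed=cfg.seed,
                )
            except ValueError as exc:
                logger.warning("abstract strategy skipped for %r: %s", d.name, exc)
        if "paraphrase" in cfg.strategies and d.human_profile:
            systems["paraphrase"] = generation.paraphrase_profile(
                d.human_profile, backend
            )
        profiles[d.name] = systems

    # --- evaluation over researchers with a human-written reference -------
    evaluable = [
        d for d in dossiers
        if d.human_profile and d.name in profiles and profiles[d.name]
    ]
    exclusions["no_human_profile"] = sum(
        1 for d in dossiers if d.name in profiles and not d.human_profile
    )
    rows = []
    corpus = [d.human_profile for d in evaluable] + [
        text for d in evaluable for text in profiles[d.name].values()
    ]
    for d in evaluable:
        ref_tokens = tokenize(d.human_profile)
        for system, text in profiles[d.name].items():
            cand_tokens = tokenize(text)
            lex = metrics_lexical.score_pair(cand_tokens, ref_tokens)
            kl = metrics_semantic.profile_kl(
                d.human_profile, text, corpus,
                epsilon=cfg.epsilon, direction=cfg.kl_direction, mode=cfg.kl_mode,
            )
            p_, r_, f1 = metrics_semantic.bert_score(cand_tokens, ref_tokens, embedder)
            row = {
                "researcher": d.name,
                "system": system,
                "bleu": lex.bleu,
                "rouge_l_f": lex.rouge_l_f,
                "meteor": lex.meteor,
                "kl": kl,
                "bert_p": p_,
                "bert_r": r_,
                "bert_f1": f1,
            }
            if mesh_vocab is not None:
                count, _terms = metrics_semantic.novel_term_count(
                    d.human_profile, [text], mesh_vocab=mesh_vocab
                )
                row["novel_terms"] = count
            rows.append(row)

    rows_df = pd.DataFrame(rows)
    if rows_df.empty:
        logger.warning("no researcher had a human-written profile; evaluation empty")
        means = pd.DataFrame()
        tests = pd.DataFrame()
    else:
        means = rows_df.drop(columns=["researcher"]).groupby("system").mean()
        tests = _pairwise_tests(rows_df, cfg.alpha)
    return ReportBundle(
        config=cfg, profiles=profiles, rows=rows_df, means=means,
        tests=tests, exclusions=exclusions,
    )


def _pairwise_tests(rows: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Paired t-tests between systems for each metric, over researchers
    scored by both systems."""
    metric_cols = [c for c in rows.columns if c not in ("researcher", "system")]
    systems = sorted(rows["system"].unique())
    out = []
    for i, a in enumerate(systems):
        for b in systems[i + 1:]:
            merged = rows[rows.system == a].merge(
                rows[rows.system == b], on="researcher", suffixes=("_a", "_b")
            )
            if len(merged) < 2:
                continue
            for m in metric_cols:
                x = merged[f"{m}_a"].to_numpy(dtype=float)
                y = merged[f"{m}_b"].to_numpy(dtype=float)
                mask = ~(np.isnan(x) | np.isnan(y))
                if mask.sum() < 2:
                    continue
                res = paired_t_test(x[mask], y[mask], alpha)
                out.append(
                    {
                        "metric": m,
                        "system_a": a,
                        "system_b": b,
                        "t": res.statistic,
                        "p": res.p_value,
                        "legend": "ns" if res.degenerate else significance_legend(res.p_value),
                        "degenerate": res.degenerate,
                    }
                )
    return pd.DataFrame(out)
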