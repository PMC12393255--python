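# scholarprofiler

Tools for building and evaluating **narrative research-interest profiles**
from a researcher's PubMed publication record.

Faculty-page research summaries go stale: researchers rarely update them, and
keyword clouds scraped from the web are a poor substitute for a fluent
paragraph. `scholarprofiler` implements a complete pipeline for generating
such profiles automatically and — just as importantly — for measuring how
machine-generated profiles differ from the ones researchers write themselves.

## What it does

1. **Records** — parse PubMed efetch XML or MEDLINE flat text into
   publication records, and keep only the publications on which the
   researcher made a primary contribution: published within a 10-calendar-year
   window and authored within the first three or last three byline positions
   (a stricter first-three-or-senior rule is available).
2. **Generation** — two strategies over a pluggable text-generation backend:
   - *MeSH-based*: the publications' MeSH keywords, bucketed into
     methodology vs. health-domain groups by MeSH tree-branch prefix
     (E/L/V vs. C/F/G), rendered into a single one-shot prompt;
   - *abstract-based*: divide-and-conquer map-reduce — publications grouped
     by dominant LDA topic, each group condensed, the summaries combined in
     a final call — so any publication count fits a bounded context window;
   - plus a *paraphrase* of the human-written profile as evaluation baseline.
   A deterministic extractive backend (top-k sentences by summed tf-idf) is
   packaged so the whole pipeline runs offline and bit-reproducibly;
   remote-LLM adapters plug into the same contract.
3. **Evaluation** — six metric families, each implemented from its
   definition and validated against independent brute-force oracles:
   - lexical: BLEU (unsmoothed clipped n-gram precision × brevity penalty),
     ROUGE-L (LCS-based F), METEOR (staged alignment + fragmentation
     penalty);
   - vocabulary shift: tf·idf weights (tf raw count, idf = ln N/df) turned
     into smoothed distributions, compared by Kullback-Leibler divergence
     D(human‖machine) = Σₜ p(t) ln p(t)/q(t);
   - novelty: the count of MeSH descriptor/entry terms present in the
     human profile but absent from every machine profile (longest-match
     phrase scan, stop words removed);
   - embedding similarity: BERTScore-style greedy cosine matching
     (precision over candidate tokens, recall over reference tokens) over a
     pluggable token embedder;
   - syntax: PoS-tag distribution, dependency-tree depth, syntactic
     complexity (mean root-to-token path length), attachment-ambiguity span
     length, and per-tag lexical diversity, over hand-suppliable or
     CoNLL-U parses;
   - agreement: Gwet's AC1 chance-corrected multi-rater coefficient with
     per-quality-band stratification, and paired t-tests with the usual
     ns/*/**/*** significance legend.
4. **Topic stability** — LDA over all abstracts (seeded, with deterministic
   multi-restart selection), dominant-topic assignment, and a per-researcher
   diversity score (unique topics / publications; < 0.3 ⇒ stable interests,
   > 0.7 ⇒ shifting) plus a year-by-topic count table.
5. **Synthetic data** — a seeded generator of researcher corpora with
   planted topic structure, planted novel MeSH terms, and rating tables with
   controlled agreement, so every claim above is testable offline.

## Worked example

```python
from scholarprofiler.synth import SynthConfig, make_corpus
from scholarprofiler.report import RunConfig, run_pipeline

dossiers, truth, mesh = make_corpus(SynthConfig(seed=7, n_researchers=6))
bundle = run_pipeline(dossiers, RunConfig(seed=7, apply_filter=False, n_topics=3),
                      mesh_vocab=mesh)
print(bundle.means[["bleu", "rouge_l_f", "kl", "bert_f1", "novel_terms"]].round(3))
```

prints

```
            bleu  rouge_l_f      kl  bert_f1  novel_terms
system
abstract     0.0      0.061  11.489    0.540          3.0
mesh         0.0      0.000  21.585    0.218          3.0
paraphrase   1.0      1.000   0.000    1.000          0.0
```

Read this as: the extractive abstract-based profiles share almost no word
sequences with the synthetic human-written profiles (BLEU 0, ROUGE-L 0.06)
yet sit at moderate embedding similarity (F1 0.54); the MeSH-based profiles,
built from keywords rather than prose, diverge more in vocabulary (KL 21.6
vs 11.5 nats); the paraphrase baseline — here the identity-like extractive
backend applied to the human profile — scores perfectly, which is exactly
the control it exists to provide. Each human profile contains 3 planted
novel MeSH concepts that neither machine profile surfaces, and the novelty
counter recovers all of them. Paired t-tests across researchers annotate
each contrast:

```
system_a   system_b          t            p legend
abstract       mesh   8.421008 3.872641e-04    ***
abstract paraphrase  -9.685573 1.992105e-04    ***
    mesh paraphrase -79.587048 5.934137e-09    ***
```

There is also a CLI for running the stages from a shell:

```bash
scholarprofiler synth --seed 7 --out corpus/
scholarprofiler report --dossiers corpus/dossiers.json --mesh-xml corpus/mesh.xml \
    --no-filter --seed 7 --out report/
scholarprofiler topics --dossiers corpus/dossiers.json --n-topics 8 --seed 7 \
    --out topics.csv
```

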