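# Methods

This note documents the models and procedures behind `scholarprofiler`, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Record filtering

A publication enters profile generation when (a) its year lies in a closed
`window_years`-calendar-year window ending at an explicit `reference_year`
(default window 10 years; the reference year is a required input rather than
the wall clock, so runs are reproducible), and (b) the researcher occupies a
primary byline position. The default positional rule keeps the first three
or last three authors; `author_rule="first3senior"` restricts the tail to
the single last (senior) position. When a byline has six or fewer authors
the two blocks overlap and first-block classification wins. Name matching is
case-folded surname plus first given-initial; if several authors match, an
affiliation substring check disambiguates. This is deliberately shallow —
full author-name disambiguation is out of scope — and records with no
publication year are dropped with a logged warning rather than guessed.

## Generation strategies

Both strategies render one-shot prompts (instruction + a single worked
example + the researcher's material) against a `GenerationBackend` contract:
`generate(prompt, max_output_tokens) -> text` plus a declared
`context_limit`. Prompt size is estimated as whitespace tokens × 1.3 (an
inflation factor approximating subword tokenizers) whenever the backend
declares no tokenizer, and a prompt exceeding the limit is an error, never a
silent truncation.

**MeSH-based.** All MeSH headings across the filtered publications are
deduplicated and bucketed by tree-branch prefix: a term whose tree numbers
all fall under E (analytical/diagnostic/therapeutic techniques), L
(information science) or V (publication characteristics) is methodology; a
term with any tree number under C (diseases), F (psychiatry/psychology) or G
(phenomena/processes) is health; anything else — including terms absent from
the loaded descriptor tree — is left unassigned and appended to the
methodology list in the prompt. A term qualifying for both goes to health,
because profiles foreground the health domain. The bucketing is
deterministic tree arithmetic rather than an extra model call, so it is
testable without any language model.

**Abstract-based (divide-and-conquer).** Abstracts are grouped by dominant
LDA topic (topic count capped at the publication count), groups exceeding
the token budget are split greedily in input order, each group is condensed
by one backend call and a final call merges the per-group summaries: k
groups cost exactly k+1 calls. Intermediate summaries are kept in a
JSON-lines provenance log.

**Paraphrase baseline.** One backend call over the human-written profile.
Its role is negative control: a text that is semantically equivalent to the
reference but lexically free, against which the reference-based metrics are
calibrated.

**Packaged backends.** The default `extractive` backend ranks the material's
sentences by summed tf-idf (sentences as the df corpus, ties to the earlier
sentence) and returns the top five in original order. It is deterministic,
so the entire generation stage is bit-reproducible given (dossier, seed,
config); `echo`, `identity` and seeded `shuffle` backends support contract
tests. Remote-LLM adapters are intentionally out of the package core.

## Evaluation metrics

**Lexical.** BLEU is the original unsmoothed sentence form: geometric mean
of clipped n-gram precisions for n = 1..4 times the brevity penalty
exp(1 − r/c) for short candidates; any zero precision zeroes the score
(profile-length texts rarely trigger this; add-epsilon smoothing is
available behind a flag). ROUGE-L is the LCS-based precision/recall/F with
β = 1. METEOR uses staged unigram alignment — exact, then stem, then
synonym, the last two via pluggable callables and off by default since no
lexical database ships — with F-mean PR/(0.9P + 0.1R) and fragmentation
penalty 0.5·(chunks/matches)³. Within a stage, candidate tokens match the
first free identical reference token left-to-right; this keeps monotone
texts in one chunk and fully reversed matches in m chunks, and is the
deterministic committed reading of chunk counting with duplicated tokens.
All metrics consume lower-cased, punctuation-stripped whitespace tokens from
the shared tokenizer.

**Vocabulary shift (KL).** Each profile is weighted by tf·idf — tf the raw
in-document count after stop-word removal, idf = ln(N/df) with no +1
smoothing, df over the full evaluation corpus with the compared pair
appended — then mapped to a probability distribution over the union
vocabulary of the pair by additive smoothing (ε = 1e−9) and renormalization.
The divergence reported is D(human ‖ machine): the human profile is the
reference distribution whose mass the machine must cover. The reverse and
symmetrized directions and a raw term-frequency mode are flags, since the
vocabulary-distribution construction admits either reading. Smoothing is
unavoidable: profile pairs share few terms, and unsmoothed KL would be
infinite for any term with machine-side zero mass. Batch mode reports the
mean and the *population* variance across researchers.

**Novelty count.** Stop-word-filtered human-profile tokens (hyphens
expanded) are scanned longest-match against the MeSH vocabulary (descriptor
names and entry terms, lower-cased, hyphen/space-normalized), and a matched
term counts as novel when its token sequence occurs in no machine text. The
controlled-vocabulary gate is what makes the count meaningful: free tokens
absent from the machine text are mostly style, while an absent MeSH concept
is a missed piece of the researcher's field. The count is antitone in the
machine text by construction.

**Embedding similarity.** Greedy matching: recall is the mean over reference
tokens of the best cosine against any candidate token, precision the mirror
image, F1 their harmonic mean; no idf weighting or baseline rescaling. The
packaged embedder maps each distinct token to a seeded random unit vector
(stable across processes via an arithmetic token key). This is context-free
on purpose: it preserves exactly the structure greedy matching measures —
identical tokens at cosine 1, unrelated tokens near 0 in high dimension —
without a model download, and a contextual transformer can be dropped in
through the same one-method contract. Scores from the random-projection
embedder are comparable within a run, not across embedders.

**Syntax.** Measures operate on dependency parses supplied through a parser
contract or CoNLL-U files; the root token heads itself. Depth and path
lengths are counted in edges. Syntactic complexity is the mean root-to-token
path length over non-root tokens (0 for a one-token sentence). Syntactic
ambiguity is operationalized as: a candidate span is the subtree of any
token whose dependency label starts with nmod/obl/acl/advcl (nested
candidates absorbed into the outermost); the span is attachment-ambiguous
when at least two NOUN/PROPN/VERB tokens precede it in the sentence; the
score is the mean token length of ambiguous spans, 0 when there are none.
This is a committed, deterministic reading of "phrases that can attach to
several components" — the testable contract is determinism given a parse.
Document scalars are means over sentences; unparseable sentences are skipped
and tallied, never silently dropped.

**Agreement.** Gwet's AC1 in its per-item form: Pa the mean over items of
the within-item rater-pair agreement rate, π_q the mean item-level category
share, Pe = Σ π_q(1−π_q)/(Q−1), AC1 = (Pa−Pe)/(1−Pe). Items with fewer than
two raters are dropped with a tally (the standard treatment of missing
ratings); Pe = 1 reports NaN. Stratified AC1 recomputes the coefficient
independently per quality band. Ratings CSVs with a `dimension` column pool
dimensions as additional items. Paired t-tests are two-sided; zero-variance
differences are reported as degenerate rather than raised, and no
multiple-testing correction is applied by default.

## Topic stability

LDA (scikit-learn's variational implementation behind a small `TopicModel`
contract) is fitted on all stop-word-filtered abstracts; 30 topics is the
institution-scale default, and a warning fires when the corpus is smaller
than the topic count. Variational EM on small corpora is initialization-
sensitive — topics merge — so `fit_lda` supports deterministic multi-restart
selection: `n_restarts` fits from seeds derived from the main seed, keeping
the best evidence lower bound. Dominant topic is the argmax with ties to the
lowest index. The diversity score is unique dominant topics over
publications with non-empty abstracts (empty-abstract publications leave
both numerator and denominator); bands are strict — below 0.3 stable, above
0.7 shifting, the boundary values intermediate.

## Synthetic data

The generator plants exactly the structure the metrics assume. Topics own
vocabularies of 40 terms (disjoint by default; `topic_overlap` shares a
fraction); abstracts are 60-token bag-of-words draws from one topic's
vocabulary. A configured fraction of researchers is "stable" (every
publication from one topic) and the rest "shifting" (all-distinct topics,
which is why the default publication range 4–8 stays at or below the
default 8 topics — otherwise a shifting researcher could not exceed the 0.7
diversity threshold). MeSH headings come from per-topic descriptor pools
present in the accompanying synthetic descriptor XML, whose tree numbers
alternate C and L branches so keyword bucketing has both kinds. Human-style
profiles are topic keywords plus planted novel MeSH concepts drawn from a
reserved descriptor pool that never enters any abstract. Rating tables give
each item a latent category that each of 3 raters copies with probability
`rating_agreement`, otherwise drawing uniformly from the remaining
categories — so agreement 1 forces AC1 = 1 and agreement 1/Q is exactly
uniform. All draws flow from one seed through named substreams, so adding a
component never shifts existing draws, and ground truth (per-publication
topic, labels, planted terms) is emitted as a machine-readable sidecar.

What the generator does **not** emulate: grammatical prose (bag-of-words
abstracts carry no syntax, which is why the syntactic suite is tested on
hand-built parse fixtures instead), realistic MeSH co-assignment patterns,
author-name ambiguity, or LLM behavior. Tests passing on this corpus
demonstrate the *measurement machinery* — recovery of planted structure,
metric-oracle agreement, calibration — not the quality of any particular
language model's profiles.

## Problem sizes and determinism

The packaged analyses run at desk scale by design: 20-researcher corpora
(~125 publications), 4–8 topics, 126–1000 rating items, and exhaustive
metric sweeps over 3-symbol alphabets up to length 5. Every random choice —
corpus generation, LDA initialization, the embedder, the shuffle backend —
derives from explicit seeds, and the end-to-end pipeline with the extractive
backend is byte-identical across runs given the same configuration.

## Known limitations

Name matching will conflate homonymous researchers sharing an affiliation
string. The unsmoothed BLEU is near 0 for most real profile pairs (as any
4-gram mismatch zeroes it); this is faithful to the original definition, and
the smoothing flag exists for exploratory use. The ambiguity measure is one
defensible operationalization among several. The random-projection embedder
gives no credit for synonymy — contextual-embedder scores will differ in
level, though not in the identities the oracle tests check. KL values depend
strongly on corpus composition and the smoothing ε, so they are comparable
only within a run configuration.
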