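# Methods

## Evaluation model

For one MeSH-like descriptor and one search strategy, relevance is defined
by indexing: the relevant set A is every citation indexed with the
descriptor (tree explosion on, i.e. indexed with the descriptor or any
tree descendant).  The retrieved set B is every citation whose
title/abstract contains at least one of the strategy's synonym phrases,
restricted to the indexed (MEDLINE-analogue) subset.  C = A ∩ B.  Then

* precision = C/B, undefined when B = 0;
* recall = C/A, undefined when A = 0;
* F₁ = 2PR/(P+R), which simplifies to 2C/(A+B); defined iff both P and R
  are, and set to 0 when C = 0 (the harmonic-mean limit, keeping F
  comparable across strategies when nothing relevant is retrieved).

Undefined values are excluded from all aggregates rather than imputed as
zero, and every table reports the count of defined values it averaged.
Restricting means to descriptors with A ≥ 1 (used at least once for
indexing) is built in via the vocabulary's use counts; B = 0 descriptors
are excluded per metric, which avoids biasing precision means downward —
the alternative (zero-filling) is available by post-processing the
per-descriptor results CSV, which carries definedness flags.

### The four strategies and the nine queries

The gold query A (`"preferred term"[mh]`) is shared by all strategies.
Each strategy contributes a retrieved query B and an intersection query C:
ATM searches the preferred term alone in `[tiab]`; the MeSH strategy ORs
the descriptor's entry terms; UMLS and CISMeF OR the synonym lists from
their mapping tables.  `[All fields]` is never emitted — expansion terms
are tagged `[tiab]` so text search cannot leak into the indexing field.
Every B and C carries `medline[sb]` once, last.  A descriptor mapped by all
four strategies therefore yields 9 distinct queries; one missing mapping
removes 2.

The A query itself carries no subset clause.  In the local engine the gold
set is intersected with the subset by default (`restrict_gold_to_subset`),
so C ≤ A and recall ≤ 1 hold exactly; the toggle can be turned off to
reproduce the unrestricted form of the query verbatim, as a live PubMed
run would issue it.

ATM is modelled as the printed single-phrase form.  Real PubMed ATM also
splits compound words and adds permuted all-fields variants; that behaviour
is unpublished and is deliberately not emulated.  Alternative synonym lists
can be supplied per descriptor through the mapping tables if a caller wants
to approximate it.

### Query rendering

Queries are ASTs (term clauses with field tags; AND/OR nodes with ordered
children) rendered deterministically: phrases are lowercased at
construction, quoted verbatim (commas and hyphens kept), tags render as
`[mh]`, `[mesh:noexp]`, `[majr]`, `[tiab]`, and the subset clause as
`medline[sb]` unquoted.  OR groups are parenthesized under AND.  Rendering
the same AST is byte-identical across runs and platforms, so rendered
strings double as cache keys for the live backend.

## Local boolean engine

Tokenization case-folds and splits on any non-alphanumeric character, so
`adult-onset diabetes` ≡ `adult onset diabetes`.  `[tiab]` phrase matching
requires the phrase tokens contiguously in order (positional postings).
Real PubMed `[tiab]` adds stemming and phrase-index quirks that are not
documented precisely; the engine's semantics are chosen to be deterministic
and fully testable, and are validated against a naive per-citation scan on
randomized corpora and query trees.

Tree explosion resolves descendants by segment-aligned tree-number prefix
(`C23.55` is not an ancestor of `C23.550`), computed per query over the
vocabulary and cached per corpus index.  `[majr]` applies the exploded set
to major-topic assignments only.

## Live backend

`EntrezBackend` issues count-only `esearch` POST requests: 3 requests/s
without an API key, 10 with one (NCBI policy), exponential backoff on 429
and 5xx, and an append-only TSV cache keyed by the exact rendered query
string with a timestamp per row.  Interrupted runs resume from the cache;
repeated runs over time keep dated counts side by side.  No citation
records are fetched — counts only.

## Comparison tables

* **Means**: unweighted arithmetic mean and sample SD (n−1 denominator)
  per strategy and metric over defined values.
* **Equality counts** (per unordered strategy pair): exact rational
  comparison by default — precision ties iff C₁B₂ = C₂B₁, F ties iff
  C₁(A₂+B₂) = C₂(A₁+B₁) — because float comparison would undercount the
  large tie blocks created by shared zero-C descriptors.  A rounded mode
  (configurable digits) exists for sensitivity checks.
* **Wins** (per ordered pair): count of descriptors where metric(s₁) −
  metric(s₂) ≥ cutoff.  The 5% cutoff is interpreted as 5 absolute
  percentage points (0.05 on the unit scale), the conventional reading for
  metrics reported as percentages.  Pairs with either side undefined are
  excluded.
* **Stratified means**: by MeSH category letter (first character of each
  tree number).  Multi-category descriptors contribute once to each of
  their categories; descriptors without tree numbers are excluded and
  counted.  A per-category best-strategy flag is attached to the table.

## Synthetic data generator

The generator emulates the statistical skeleton of a MEDLINE evaluation:

* `n_descriptors` descriptors with unique two-token preferred terms and
  random tree placements over ≥ 3 category letters up to `tree_depth`;
* per-strategy synonym tables sampled from a per-descriptor phrase pool,
  so strategies overlap but never coincide (identical draws are nudged
  apart, and MeSH entry-term counts default to ≥ 2 so the MeSH expansion
  never collapses onto ATM's single-phrase query);
* per citation and descriptor, indexing is Bernoulli(`pi`); each of the
  descriptor's phrases appears in the text with probability `alpha` when
  indexed, `beta` otherwise, independently; subset membership is
  Bernoulli(`subset_prob`); major-topic flags Bernoulli(`major_topic_prob`)
  among indexed terms.

Defaults: `pi=0.05`, `alpha=0.7`, `beta=0.01`, `subset_prob=1`,
`major_topic_prob=0.3`, synonym counts MeSH 2–4, UMLS 2–8, CISMeF 1–6 —
small corpora with strong but imperfect text signal and sparse noise,
sized so every module is exercised in seconds.

Phrases are two-token strings whose first token is globally unique, from an
alphabet disjoint from the filler tokens that separate embedded phrases; a
phrase therefore occurs in a text iff the generator put it there.  That
makes the closed forms exact: with k independent synonyms, expected recall
is 1−(1−alpha)^k and expected precision is
pi·p_rel / (pi·p_rel + (1−pi)·p_irr) with p_rel = 1−(1−alpha)^k and
p_irr = 1−(1−beta)^k.  An eligibility post-pass force-indexes any
descriptor that drew no citation, before the occurrence draws, so the model
stays exact for forced citations too.

What the generator does **not** model: co-indexing correlation between
descriptors, realistic term-frequency or abstract-length distributions,
indexing depth, or PubMed stemming.  Passing tests therefore demonstrate
the correctness of the query construction, counting and aggregation
machinery — not the real-MEDLINE performance of any strategy, which
depends on live data.

Parameter-recovery checks use `tree_depth=(1,1)` (flat vocabularies):
with explosion active, a descendant's indexing inflates A with citations
that carry the descendant's phrases rather than the ancestor's, so the
closed forms above hold only when no descriptor has descendants.  Tree
behaviour is tested separately via the explosion monotonicity checks.

## Problem sizes and numerical conventions

The test suite and acceptance script size their inputs so the full run
completes in well under a minute: the query-count identities run at the
full 26,636-descriptor scale (construction only, no corpus); engine/oracle
equivalence uses 1000 randomized pairs over corpora of 40–120 citations;
parameter recovery uses 50,000 citations over 4 flat descriptors with
agreement asserted within 3 binomial standard errors; the trade-off check
uses 250 descriptors × 2000 citations.  All randomness flows from explicit
integer seeds through `numpy.random.default_rng` / `random.Random`; reruns
are byte-identical, including corpus files and result CSVs.

Degenerate inputs are handled explicitly: an empty synonym list skips the
strategy for that descriptor (no empty OR groups); a phrase with no tokens
matches nothing and is logged; a descriptor absent from corpus indexing
yields A = 0 and an undefined recall rather than an error.
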