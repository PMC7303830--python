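# meshexpand

Automatic evaluation of semantic query-expansion strategies for
MeSH-descriptor searches of MEDLINE/PubMed.

## The problem

Biomedical literature searches built from a single MeSH descriptor can be
phrased in several ways: let PubMed's automatic term mapping (ATM) handle
the preferred term, or expand the query with synonyms drawn from the MeSH
entry terms, from UMLS concept mappings, or from custom cross-vocabulary
mappings (CISMeF).  Which expansion works best varies by descriptor, and
manual assessment only ever covers a handful of descriptors.

`meshexpand` implements an automatic assessment that scales to a whole
vocabulary.  Using NLM indexing as the gold standard — a citation is
relevant to a descriptor iff indexers assigned that descriptor to it —
three citation counts are measured per descriptor and strategy:

| set | meaning | query |
|-----|---------|-------|
| A | relevant citations | `"preferred term"[mh]` |
| B | retrieved citations | `("synonym 1"[tiab] OR "synonym 2"[tiab] OR …) AND medline[sb]` |
| C | relevant citations retrieved | `"preferred term"[mh] AND (…) AND medline[sb]` |

from which precision = C/B, recall = C/A, and F₁ = 2PR/(P+R) follow.  With
the shared gold query, a fully mapped descriptor yields nine distinct
queries (1 A + 4 B + 4 C across ATM/MeSH/UMLS/CISMeF); at full MeSH scale
(26,636 descriptors used at least once for indexing) that is 239,724
queries.  Per-descriptor metrics are aggregated into per-strategy means and
SDs, exact-tie counts per strategy pair, win counts at a cutoff (default 5
percentage points), and means stratified by MeSH category letter.

Counts come from either backend:

* a **local boolean engine** over a citation corpus — positional phrase
  index for `[tiab]`, descriptor indexing with tree explosion for `[mh]`
  (`[mesh:noexp]` and `[majr]` variants included), subset filtering for
  `medline[sb]`;
* the **live NCBI E-utilities** (`esearch`, count-only), with rate
  limiting, retries and an append-only query/count cache for resumable
  runs.

A synthetic-data generator produces MEDLINE-like vocabularies and corpora
under a stated probabilistic model (indexing probability `pi`, synonym
occurrence probability `alpha` in relevant citations, `beta` elsewhere), so
expected precision and recall are known in closed form and the whole
pipeline is testable offline.

## Worked example

```sh
meshexpand generate --n-descriptors 200 --n-citations 5000 --seed 7 \
    --out-vocabulary vocab.json --out-corpus corpus.jsonl
meshexpand count --vocabulary vocab.json
meshexpand evaluate --vocabulary vocab.json --corpus corpus.jsonl --output-dir run
```

`count` prints `1800` — nine queries for each of the 200 fully mapped
descriptors.  `evaluate` writes `run/results.csv` (one row per
descriptor-strategy with A, B, C and the three metrics), the comparison
tables (`means.csv`, `equality.csv`, `wins.csv`, `category_means.csv`,
`report.json`) and a run manifest.  The per-strategy means for this seed:

```
          precision_mean  recall_mean  f_measure_mean
strategy
ATM                0.794        0.556           0.625
MESH               0.645        0.768           0.662
UMLS               0.547        0.791           0.606
CISMEF             0.623        0.743           0.632
```

The generator gives ATM a single search phrase and the expansion
strategies progressively more synonyms, so the classic trade-off is
visible: expansion raises recall (0.556 → 0.79) at the cost of precision
(0.794 → 0.55).  The wins table counts descriptors where one strategy
beats another by at least 5 points, e.g. ATM has better precision than
MESH on 195 of 200 descriptors while MESH has better recall on 197 —
rankings that single means would hide.

The library mirrors the CLI: `build_query_set` → `counts_for_query_set` →
`compute_metrics` → `compare`, plus `EntrezBackend` for live PubMed counts.

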