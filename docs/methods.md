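# Methods

## Model

`semgo` implements ontology-grounded document retrieval in two stages.

**Preprocessing.** An OBO 1.2 ontology is reduced to the attributes the
retrieval task needs — accession, name, namespace, synonyms with scope,
typed relations — and decomposed by namespace into three subontology tables
(component, function, process) sharing one synonym table and one relation
table, all in a single sqlite artifact. A relation line inside a stanza is
stored with that stanza's accession as the owner (GID) and the relation's
target as parent; inverse (child) edges are not materialized. The corpus is
then annotated: each document is scanned for every vocabulary string —
canonical names plus synonym surfaces — and per-document frequencies are
written to an annotated index (paper + term tables in the same artifact).
Searching later touches only this index, never the raw text.

**Search.** A query asserts up to three term names, one per subontology.
Each is expanded depth-1 into the canonical name, all synonyms with scope,
and all direct relation-target names with type; every inferred string is a
separate probe against the index. Probe hits are unioned into unique
documents, each document is rearranged into the frequency vector
[T_cc, T_mf, T_bp, R_cc, R_mf, R_bp, S_cc, S_mf, S_bp], and scored

    D_Rank = W_T (T_cc+T_mf+T_bp) + Σ_i S_i·W_syn(i) + Σ_j R_j·W_rel(j),

sorted descending, ties by ascending document id.

## Assumptions

- A document is "about" a concept in proportion to the raw frequency of the
  concept's surface strings; no length or collection-frequency
  normalization is applied (the scoring is intentionally the plain weighted
  sum, not TF-IDF/BM25).
- Synonym and relation classes are closed sets: scopes EXACT / NARROW /
  BROAD / RELATED, relation types is_a / part_of / has_part / regulates.
  Anything else in the input (e.g. `occurs_in`, systematic synonym scopes)
  is dropped and logged; `positively_regulates` / `negatively_regulates`
  are folded into `regulates`. The scope spelling "RELATD", seen in the
  wild, is read as RELATED.
- Expansion is depth-1 by design: only direct relation targets, no
  grandparents, no transitive closure, no DAG reasoning.

## Matching rules

Occurrence counting is case-insensitive and boundary-delimited: a match
counts when flanked by start/end of text, whitespace, or punctuation
(operationally: any non-alphanumeric character). There is deliberately no
bare-substring fallback — it would count `binding` inside `unbinding`.
There is also no stemming or lemmatization, so `binds` does not match
`binding`; this mirrors dictionary-style concept annotation.
Nested vocabulary strings are counted independently: text containing
`alkaline phosphatase activity` also yields one occurrence of the distinct
vocabulary string `phosphatase activity`. Synonym hits are indexed under
the synonym's own surface string; the link to the owning concept is made at
query time. A surface string serving several concepts keeps a single index
row, owned (deterministically) by the canonical-name owner, else the
smallest accession.

## Parameters

| parameter | default | meaning |
|---|---|---|
| W_T | 10 | weight of an asserted-term occurrence (shared by cc/mf/bp; the formula scales their sum) |
| W_syn | 8, 7, 6, 5 | NARROW, EXACT, RELATED, BROAD synonym occurrence weights |
| W_rel | 4, 3, 2, 1 | is_a, has_part, part_of, regulates relation-target weights |

The defaults encode a strict priority ladder — asserted term > any synonym
> any relation — on the reasoning that the asserted term is exactly what
the researcher wants, a synonym is the same concept in different wording,
and a relation target is related but more generic. All nine weights are
unitless multipliers on occurrence counts, must be finite and ≥ 0, and can
be overridden per key in a `key = value` weight file. Scores are floats;
rank ties are compared after rounding to 1e-9 so platform float noise
cannot reorder the deterministic id-based tie-break.

## Synthetic fixtures

The fixture generator emulates the two inputs the pipeline needs, with
known ground truth rather than realism:

- **Ontology**: a valid OBO 1.2 file containing hand-coded real GO records
  (binding, chromosome, nucleus, alkaline phosphatase activity, host,
  growth, and the brain development / organ development / central nervous
  system development triple, with their published synonyms and relations)
  plus seeded synthetic filler terms cycling through the three namespaces,
  optionally flagged obsolete. Filler names are built from an invented word
  list with per-term numeric suffixes, so no filler string can collide
  with, or nest inside, the hand-coded vocabulary.
- **Corpus**: generated from a planting plan mapping (document, vocabulary
  string) to an intended count. Each planted occurrence is placed between
  filler words drawn from a fixed non-biological list disjoint from every
  vocabulary word, consecutive planted tokens are always separated by at
  least one filler word, and plans that would make counts ambiguous are
  rejected: a planted string nested in another planted string of the same
  document, and — when the full vocabulary is supplied — a planted string
  that contains *any* vocabulary string (e.g. `cell nucleus` contains
  `nucleus`). Under these rules the annotated index provably equals the
  plan, which is what the end-to-end tests assert.

What passing on fixtures does **not** show: behaviour on real biomedical
prose — inflected mentions, abbreviations, hyphenation variants, nested GO
phrases at natural density, or OBO files using tags outside the subset
parsed here. The fixtures certify the mechanics (partitioning, counting,
expansion, union, scoring), not annotation recall on real text.

## Numerical and procedural choices

- Problem sizes used by the default checks — a 200-stanza ontology, a
  100-document planted corpus, 1000 random vector/weight pairs for the
  scoring oracle — are comfortably past the point where the invariants
  would catch systematic errors, while keeping the whole suite at a few
  seconds.
- Document ordering, TSV dumps, and corpus generation are deterministic:
  documents are processed in id order, per-document RNG streams are derived
  from `(seed, paper_id)`, and rebuilding from identical inputs is
  byte-identical.
- Obsolete ontology terms are parsed (and flagged) but excluded from every
  table: indexing obsolete names would pollute annotation.
- Relation-target names missing their inline `! name` comment are resolved
  from sibling stanzas in the same file; targets defined nowhere keep an
  empty name and simply never match a probe.
- Degenerate inputs: an empty OBO stream is an empty ontology (not an
  error); an empty corpus builds a valid empty index; a query matching
  nothing returns an empty ranked list with a zero-filled summary and
  success status. Malformed stanzas and unresolvable asserted terms are
  hard errors that name the offending record.

## Known limitations

- Dictionary matching only: recall on real text is bounded by exact surface
  forms; no morphological normalization or abbreviation expansion.
- Depth-1 expansion cannot retrieve documents that mention only a
  grandparent concept.
- The relation weight is applied per relation *target occurrence*
  regardless of which asserted term induced it; two asserted terms sharing
  a relation target each contribute their own probe, but the shared index
  row is counted once per probe role entry.
- Single-threaded; index rebuilds are full, not incremental.
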