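# semgo — semantic Gene Ontology document retrieval

`semgo` is a small information-retrieval system for biological literature.
Instead of matching raw keywords, it describes each document by the Gene
Ontology (GO) concepts it mentions and lets a researcher retrieve documents
by asserting up to three terms — one per GO subontology: a cellular
component (cc), a molecular function (mf), and a biological process (bp) —
in any combination.

It is aimed at researchers and text-mining practitioners who need
"documents that mention this function and/or this process in this cellular
component" rather than a bag-of-words search.

## What it does

1. **Ontology decomposition.** An OBO 1.2 flat file is parsed and its
   `[Term]` stanzas are routed by namespace into three normalized tables
   (component, function, process) with shared synonym and relation tables.
   Synonym scopes are GO's EXACT / NARROW / BROAD / RELATED; relation types
   are `is_a`, `part_of`, `has_part`, `regulates`.
2. **Corpus annotation.** Every plain-text document is scanned for every
   vocabulary string (canonical names and synonym surfaces) with
   case-insensitive, boundary-delimited matching, producing an annotated
   index of per-document concept frequencies. Searches then run against
   this compact index, not the raw corpus.
3. **Query expansion.** Each asserted term is expanded depth-1 with its
   stored synonyms and its direct relation targets — asserting the process
   *brain development* also probes *organ development* (`is_a` parent) and
   *central nervous system development* (it is `part_of` that process).
4. **Ranking.** Hits are unioned into unique documents and each document's
   frequency vector [T_cc, T_mf, T_bp, R_cc, R_mf, R_bp, S_cc, S_mf, S_bp]
   is scored with the weighted sum

   ```
   D_Rank = W_T (T_cc + T_mf + T_bp)
          + Σ_i S_i · W_syn(i)      i: NARROW, EXACT, RELATED, BROAD
          + Σ_j R_j · W_rel(j)      j: is_a, has_part, part_of, regulates
   ```

   with defaults W_T=10 > W_syn = (8, 7, 6, 5) > W_rel = (4, 3, 2, 1):
   the asserted term outranks any synonym, any synonym outranks any
   relation. Weights are user-configurable via a key/value file.

## Worked example

The package ships a fixture generator that writes a valid OBO file (real GO
records for *binding*, *chromosome*, *nucleus*, *alkaline phosphatase
activity*, *host*, *growth*, *brain development* and friends, plus synthetic
filler terms) and a corpus with known planted occurrence counts:

```sh
semgo make-fixtures --out fx --n-docs 6 --seed 3 --n-filler 10
semgo build-index --obo fx/fixture.obo --corpus fx/corpus --out fx/index.db
semgo search --index fx/index.db --mf binding --bp growth
```

prints

```
Term Name: binding
ID: GO:0005488
Type: Function
Relations: molecular_function (is_a)
Synonyms: ligand (NARROW)

Term Name: growth
ID: GO:0040007
Type: Process
Relations: biological_process (is_a)
Synonyms: growth pattern (RELATED); nondevelopmental growth (RELATED)

class	cc	mf	bp
terms	0	0	1
relations	0	0	1
synonyms	0	1	0
union	3 documents

PaperID	DRank
doc4.txt	32
doc1.txt	20
doc3.txt	10
```

Reading the output: the two metadata blocks show how each asserted term was
expanded. The class table counts, per subontology, the documents hit by
the asserted terms themselves, by their relation targets, and by their
synonyms; `union` is the number of unique documents retrieved. In the
ranked list, `doc4.txt` contains the NARROW synonym *ligand* 4 times
(4 × 8 = 32), `doc1.txt` contains *growth* twice (2 × 10 = 20), and
`doc3.txt` contains *growth* once (1 × 10 = 10) — higher D_Rank means a
closer match to the asserted terms.

The same pipeline is available as a library:

```python
import semgo

store = semgo.decompose(semgo.parse_obo(open("fx/fixture.obo").read()))
index = semgo.build_index(semgo.load_corpus("fx/corpus"), store)
q = semgo.expand(store, semgo.AssertedQuery(mf="binding", bp="growth"))
hits = semgo.search_index(index, q)
records = semgo.rearrange(hits, semgo.union_documents(hits))
for r in semgo.rank_results(records):
    print(r.paper_id, r.d_rank)
```

## Scope

Single-threaded, plain-text corpora only (one UTF-8 file per document); no
PDF/XML ingestion, no stemming or disambiguation, no boolean query algebra,
and deliberately no TF-IDF/BM25 — the ranking is the plain weighted sum
above. See `docs/methods.md` for the model details and limitations.
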