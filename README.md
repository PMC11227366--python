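# ontosig

Dictionary-based concept recognition for ontologies whose terms are built
from common-language words — the motivating case is annotating clinical and
biomedical text with Human Phenotype Ontology (HPO) concepts, but any
ontology with labels and synonyms works.

Phenotype vocabulary is lexically variable: *short phalanx of the thumb*,
*shorter phalanges of the thumbs* and *shortening of the phalanx* all name
the same concept, and lemmatization does not reconcile them (the lemma of
*shorter* is *short*, of *shortening* is *shorten*). `ontosig` addresses
this with three pieces:

1. **Cluster vocabulary** — a strict partition of tokens into clusters of
   morphologically equivalent forms (`short / shorter / shorten /
   shortening`), built deterministically (shared 4-letter prefix + shared
   canonical stem, after folding localized spellings such as
   *haemorrhage / hemorrhage*), or loaded from a plain-text cluster file so
   any externally built clustering can be plugged in.
2. **Signature index** — each term surface (label or synonym) is tokenized,
   stop words/auxiliaries/conjunctions are removed, each remaining token is
   replaced by its cluster ID, and the ID set is serialized as a
   lexicographically sorted key plus the filtered token count:
   `Increased size of cranium` → `("C2-C26-C35", 3)`. The key is
   order-insensitive; the length separates surfaces that repeat a cluster.
3. **Recognizer** — text tokens are looked up once each in the index
   (O(tokens)); maximal runs of in-index tokens (stop words transparent,
   unknown tokens and punctuation breaking) become candidates; every
   contiguous window of a candidate is one hash lookup of its signature.
   Matching is linear in the number of windows and insensitive to token
   order inside a window (*short phalanx* ≡ *phalanx shortening*).

Evaluation utilities compute document-level (per-document concept-ID sets)
and mention-level (positioned spans, exact or overlap) precision, recall and
F1 = 2PR/(P+R), and align gold corpora annotated against older ontology
releases by resolving retired concept IDs through the `alt_id` property.

A fixtures module generates fully synthetic mini-ontologies, cluster files,
document corpora with mentions planted at known offsets, and gold files, so
everything is testable without downloading an ontology or corpus.

## Worked example

```python
from ontosig import Concept, annotate, build_clusters, build_index

tokens = {"increase", "increased", "increasing", "size", "sizes",
          "cranium", "crania", "macrocephaly", "hernia", "hernias",
          "umbilical"}
vocab = build_clusters(tokens)
concepts = [
    Concept("HP:0000256", "Macrocephaly",
            ["Increased size of cranium"], ["EXACT"]),
    Concept("HP:0100790", "Hernia"),
    Concept("HP:0001537", "Umbilical hernia"),
]
index = build_index(concepts, vocab)

text = ("Examination shows an increasing size of the cranium. "
        "Small umbilical hernia.")
for m in annotate(text, index, policy="all"):
    print(f"{m.start:3d} {m.end:3d}  {m.surface!r:34}  {m.concept_id}  "
          f"({m.matched_term})")
```

prints

```
 21  51  'increasing size of the cranium'    HP:0000256  (Increased size of cranium)
 59  75  'umbilical hernia'                  HP:0001537  (Umbilical hernia)
 69  75  'hernia'                            HP:0100790  (Hernia)
```

*increasing* matches through its cluster even though only *increased* occurs
in the indexed synonym; the stop words *of*/*the* are transparent inside the
span; *hernia* is additionally reported as a concept nested inside
*umbilical hernia* (use `policy="longest-only"` to suppress nested
mentions). Offsets are 0-based, end-exclusive, into the original text.

## Command line

```sh
ontosig build-clusters --tokens tokens.txt --out clusters.txt
ontosig index    --ontology hp.obo --clusters clusters.txt --out index.json
ontosig annotate --index index.json --input docs.jsonl --policy all --out mentions.tsv
ontosig evaluate --index index.json --corpus docs.jsonl --gold gold.tsv --level doc
ontosig fixtures --seed 1 --out fixtures/
```

Exit codes: 0 success, 1 usage error, 2 data error. Run counters (documents,
tokens, candidates, lookups, mentions) are logged to stderr.

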