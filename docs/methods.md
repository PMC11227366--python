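# Methods

## The recognition model

`ontosig` implements dictionary-based concept recognition in which boundary
detection is driven by the index rather than by a candidate generator. The
pipeline has three stages.

**Cluster vocabulary.** Lexical variability is handled before any text is
seen, by partitioning a token vocabulary into clusters of morphologically
equivalent forms. Two tokens share a cluster iff, after spelling
normalization, they share (a) the same 4-letter prefix and (b) the same
canonical stem. Tokens shorter than 4 letters are grouped by their full
text: the prefix rule is undefined for them, and short tokens are rarely
morphological variants of one another. Only letters-only tokens ("proper
words") are clustered. The partition is strict — every token belongs to
exactly one cluster — because recognition replaces each text token by *the*
cluster ID it maps to; overlapping clusters would make that lookup
ambiguous. Cluster IDs (`C1, C2, …`) are opaque and assigned in
lexicographic order of each cluster's smallest member, which makes rebuilds
bit-reproducible. Externally built clusterings (however produced) can be
supplied as a plain-text file, one cluster per line; IDs are then the
1-based line numbers.

**Indexing.** For every label and synonym of every non-obsolete concept:
tokenize (split on any non-alphanumeric), remove blacklisted tokens (stop
words, auxiliary/copular verbs, conjunctions), replace each remaining token
by its cluster ID, and store the signature — the de-duplicated,
lexicographically sorted, `-`-joined ID string — together with the filtered
token count. The count, not the key alone, is what disambiguates the rare
surface that uses one cluster twice. The index retains only: the signature
map (to the concept IDs and original surfaces, returned to the user on a
match), the token map, and the blacklist. The token map contains the *full*
membership of every cluster that contributed at least one token to at least
one indexed surface (variant closure) — this is the mechanism by which a
morphological variant never written in the ontology still matches — and
nothing else.

**Recognition.** The document is tokenized with character offsets; each
word token is looked up once (blacklist first, then token map), giving it
one of four states: known (carries a cluster ID), blacklisted, unknown, or
punctuation break. Maximal runs of known tokens form candidates; every
contiguous window of a candidate is looked up by signature. Counters verify
the complexity contract directly: token lookups = word-token count, and
signature lookups = Σ k(k+1)/2 over candidates of length k.

## Numerical and procedural choices

- **Blacklist transparency.** Blacklisted tokens are transparent *inside* a
  candidate but never start or end a mention's token set. Indexed
  signatures exclude stop words, so text-side stop words must neither break
  a run nor contribute to the window length; otherwise "increased size of
  the cranium" could never match a surface indexed without "of"/"the".
  Mention spans run from the first to the last matched word token, so
  interior stop words are included in the reported surface.
- **Punctuation.** Any non-alphanumeric, non-whitespace character between
  words breaks continuity (hyphens included — the conservative reading;
  `tokenize_text` keeps the rule in one place if a joiner policy is ever
  needed). Whitespace alone never breaks.
- **Spelling normalization.** Ordered substitutions `ae→e`, `oe→e` applied
  to a fixed point, before prefix grouping, so *haemorrhage*/*hemorrhage*
  fall into one prefix group. Running to a fixed point guarantees
  idempotence even on degenerate inputs.
- **Stemmer.** The default is an iterative suffix stripper (strip
  inflectional/derivational suffixes, then tidy a trailing silent *e* and a
  doubled final consonant, to a fixed point; never leaving fewer than 4
  letters). A conservative inflectional stemmer is deliberately not the
  default: it keeps *shorter* and *shorten* apart and would fragment
  exactly the derivational families this method needs merged. The stemmer
  is a pluggable `str -> str` strategy registered by name; the pinned
  default makes cluster builds reproducible. Over-stemming inside a prefix
  group (e.g. *chicken→chick*) costs little: it can only merge tokens that
  already share their first four letters.
- **Blacklist content.** Shipped as a package data file (~110 entries:
  determiners/prepositions/pronouns, auxiliary and copular verbs,
  conjunctions) and overridable per run. A pinned artifact, not a library
  call, so that index builds are reproducible.
- **Synonym scope.** All synonym types are indexed by default;
  `exact_synonyms_only` restricts to EXACT.
- **Numerals.** Ontology surfaces may contain digit-bearing tokens ("type
  1"); these get implicit singleton clusters keyed by their own (lowercase)
  text, which cannot collide with `C`-prefixed IDs. Letters-only tokens not
  covered by the vocabulary make a surface unindexable; such surfaces are
  counted and skipped, never silently dropped.
- **Ambiguity and duplicates.** A signature shared by several concepts
  yields one mention per concept, flagged ambiguous. The same concept
  matched at the same span by different windows is deduplicated; different
  spans stay distinct (mention-level scoring needs positions).
- **Policies.** `all` (default) returns every matched window, including
  nested concepts (*hernia* inside *umbilical hernia*); `longest-only`
  greedily keeps the longest non-overlapping mentions, ties to the
  leftmost.
- **Window cap.** Candidates are decomposed only into windows of ≤ 10 known
  tokens, bounding the quadratic window count per candidate; filtered term
  surfaces are far shorter than 10 tokens in practice.
- **Evaluation.** Micro-averaging is the default (counts summed over
  documents before P/R/F1); macro is available behind a flag. Mention
  matching is one-to-one greedy in document order, so one prediction cannot
  satisfy duplicated gold. P, R and F1 are defined as 0 when their
  denominators vanish. Corpus alignment maps a gold ID to: itself if
  current; the owning concept if it is someone's `alt_id` (ambiguous
  ownership is an error); the `replaced_by` target if it is an obsolete
  term's own ID; otherwise it is an orphan — reported, and excluded from
  scoring.

## The synthetic data generator

`fixtures.generate` emulates the structure the method assumes: multi-token
term surfaces, morphological variants of each token, stop words interleaved
inside surfaces, shuffled token order in synonyms and in planted text, and
obsolete concepts that donate their ID as an `alt_id` of their replacement.
Tokens are pronounceable CV-syllable strings over a vowel set without *e*,
keeping them inert under spelling normalization; distractor tokens come
from a disjoint pool. Concepts draw disjoint cluster sets and all surfaces
of one concept reuse the same set, so no surface nests inside another and
no signature collides by accident — which is what makes the planted ledger
an exact oracle (precision = recall = 1 is the *required* outcome on a
clean bundle, and any deviation is a recognizer defect).
`unseen_variant_fraction` plants that fraction of mentions using a token
variant absent from the cluster file; mention-level recall must then drop
by exactly the planted fraction.

Defaults (6 concepts, 1–3 tokens per surface, 2–4 variants per token, 4
documents of 2–5 mentions, distractor rate 0.3, obsolete fraction 0.25)
are sized so a bundle exercises every code path — multi-token and
single-token surfaces, variants, stop words, obsolete terms — while staying
small enough that exhaustive window enumeration is practical as a
cross-check.

What passing on these corpora does **not** show: performance on real
clinical prose. The generator plants no coordination ("short and broad
toes"), no negation or context ("no hernia", double-blind *blindness*), no
non-contiguous mentions ("dysplastic left kidney"), no typos, and no
genuinely ambiguous vocabulary. Those are known limitations of the
dictionary approach itself, out of scope here; scores on real corpora are
governed by the quality of the supplied cluster vocabulary and ontology
synonymy, which the synthetic bundles idealize.

## Problem sizes used by the checks

The test suite and `scripts/acceptance.py` run on generated bundles of 2–8
concepts and 1–20 documents; the brute-force cross-check sweeps 200 random
bundles (a few hundred documents), the metric-invariant check 1000 random
gold/prediction pairs, and the counter check 100 documents. These sizes
fully cover the combinatorics of the method (every window of every
candidate) while keeping the whole verification run in the order of
seconds.

## Known limitations

- Matching is bound to the supplied cluster vocabulary and the ontology's
  explicit labels/synonyms; unseen synonyms do not match (measured directly
  by `unseen_variant_recall_error`).
- One reading of nested matching is implemented (sub-windows are always
  looked up, whether or not the enclosing window matched); the
  `longest-only` policy provides the other behaviour at output time.
- The OBO reader takes labels, synonyms, `alt_id`, obsolescence and
  `replaced_by` only; no OWL reasoning or cross-ontology mapping.
- Character offsets assume lowercasing preserves string length; this holds
  for the Latin-script clinical text the tool targets.
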