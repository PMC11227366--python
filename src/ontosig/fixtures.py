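"""Self-contained synthetic fixtures: mini-ontology, clusters, corpus, gold.

Everything the other modules consume can be generated here with no
download: an OBO mini-ontology whose concepts have multi-token labels and
synonyms (including obsolete concepts that donate their ID as an alt_id of
their replacement), the cluster file covering every token's morphological
variants, a JSONL document corpus with mentions planted at known character
offsets, and the matching gold TSV.

The generator is deliberately adversarial-free: concepts draw their tokens
from disjoint cluster sets and every surface of a concept uses the same
cluster set, so no surface nests inside another and no accidental signature
collisions occur.  That makes the planted-truth ledger an exact oracle: with
no unseen variants planted, the recognizer must recover precisely the
planted mentions (P = R = 1).  Setting ``unseen_variant_fraction`` plants
that fraction of mentions with a token variant absent from the cluster file,
which lowers mention-level recall by exactly that fraction — a controlled
degradation useful for testing the evaluation stack.

Synthetic tokens are pronounceable CV-syllable strings; distractor tokens
come from a disjoint pool and never collide with any indexed cluster.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .cluster_vocab import ClusterVocabulary, load_clusters
from .evaluation import GoldAnnotation, write_gold_tsv
from .ontology_index import Concept, ConceptIndex, build_index, default_blacklist

__all__ = ["FixtureSpec", "FixtureBundle", "generate"]

_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aiou"  # no "e": keeps synthetic stems inert under spelling rules
_VARIANT_SUFFIXES = ("", "s", "ing", "ed", "er")
_STOPWORDS_INSIDE = ("of", "the", "in")


@dataclass
class FixtureSpec:
    """Knobs for one synthetic bundle; deterministic given ``seed``."""

    n_concepts: int = 6
    synonyms_per_concept: tuple[int, int] = (1, 2)
    tokens_per_surface: tuple[int, int] = (1, 3)
    morph_variants_per_token: tuple[int, int] = (2, 4)
    n_docs: int = 4
    mentions_per_doc: tuple[int, int] = (2, 5)
    distractor_token_rate: float = 0.3
    obsolete_fraction: float = 0.25
    unseen_variant_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("synonyms_per_concept", "tokens_per_surface",
                     "morph_variants_per_token", "mentions_per_doc"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"empty range for {name}: {lo}..{hi}")
        for name in ("distractor_token_rate", "obsolete_fraction",
                     "unseen_variant_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_concepts <= 0 and (
            self.n_docs > 0 and self.mentions_per_doc[1] > 0
        ):
            raise ValueError("unsatisfiable spec: zero concepts with positive mentions")
        if self.tokens_per_surface[0] < 1:
            raise ValueError("surfaces need at least one token")


@dataclass
class FixtureBundle:
    """In-memory bundle plus writers for the on-disk formats."""

    concepts: list[Concept]
    cluster_lines: list[str]
    documents: list[tuple[str, str]]
    gold: list[GoldAnnotation]
    # ledger rows: (doc_id, start, end, surface_used, concept_id, recoverable)
    ledger: list[tuple[str, int, int, str, str, bool]] = field(default_factory=list)

    def vocabulary(self) -> ClusterVocabulary:
        import io

        return load_clusters(io.StringIO("\n".join(self.cluster_lines) + "\n"))

    def index(self, blacklist: Optional[set[str]] = None) -> ConceptIndex:
        return build_index(
            self.concepts,
            self.vocabulary(),
            blacklist=blacklist or default_blacklist(),
            ontology_version="fixture",
        )

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "ontology": out / "ontology.obo",
            "clusters": out / "clusters.txt",
            "documents": out / "documents.jsonl",
            "gold": out / "gold.tsv",
            "ledger": out / "ledger.tsv",
        }
        paths["ontology"].write_text(self._obo_text(), encoding="utf-8")
        paths["clusters"].write_text("\n".join(self.cluster_lines) + "\n", "utf-8")
        with open(paths["documents"], "w", encoding="utf-8") as fh:
            for doc_id, text in self.documents:
                fh.write(json.dumps({"id": doc_id, "text": text}) + "\n")
        write_gold_tsv(self.gold, paths["gold"], surfaces={
            (d, s, e): surf for d, s, e, surf, _, _ in self.ledger
        })
        with open(paths["ledger"], "w", encoding="utf-8") as fh:
            fh.write("# doc_id\tstart\tend\tsurface\tconcept_id\trecoverable\n")
            for row in self.ledger:
                fh.write("\t".join(str(x) for x in row) + "\n")
        return paths

    def _obo_text(self) -> str:
        lines = ["format-version: 1.2", "ontology: fixture", ""]
        for c in self.concepts:
            lines.append("[Term]")
            lines.append(f"id: {c.concept_id}")
            if c.label:
                lines.append(f"name: {c.label}")
            for alt in c.alt_ids:
                lines.append(f"alt_id: {alt}")
            for syn in c.synonyms:
                lines.append(f'synonym: "{syn}" EXACT []')
            if c.obsolete:
                lines.append("is_obsolete: true")
                if c.replaced_by:
                    lines.append(f"replaced_by: {c.replaced_by}")
            lines.append("")
        return "\n".join(lines)


def _make_stem(rng: random.Random, taken: set[str]) -> str:
    while True:
        n_syll = rng.randint(2, 3)
        stem = "".join(
            rng.choice(_CONSONANTS) + rng.choice(_VOWELS) for _ in range(n_syll)
        ) + rng.choice(_CONSONANTS)
        if stem not in taken and not any(stem[:4] == t[:4] for t in taken):
            taken.add(stem)
            return stem


def generate(spec: FixtureSpec) -> FixtureBundle:
    """Build a deterministic bundle from ``spec`` (same seed, same bundle)."""
    spec.validate()
    rng = random.Random(spec.seed)
    taken: set[str] = set()

    # one cluster of morphological variants per synthetic stem
    n_stems_needed = spec.n_concepts * spec.tokens_per_surface[1] + 2
    clusters: list[list[str]] = []
    for _ in range(n_stems_needed):
        stem = _make_stem(rng, taken)
        k = rng.randint(*spec.morph_variants_per_token)
        suffixes = [""] + rng.sample(_VARIANT_SUFFIXES[1:], min(k - 1, 4))
        clusters.append([stem + suf for suf in suffixes])
    cluster_lines = [" ".join(members) for members in clusters]

    # concepts draw disjoint cluster sets; all surfaces of one concept reuse
    # the same set (different variants / order) so nothing nests
    concepts: list[Concept] = []
    pool = list(range(len(clusters)))
    next_cluster = 0
    for ci in range(spec.n_concepts):
        k = rng.randint(*spec.tokens_per_surface)
        if next_cluster + k > len(pool):
            stem = _make_stem(rng, taken)
            clusters.append([stem])
            cluster_lines.append(stem)
            pool.append(len(clusters) - 1)
        own = pool[next_cluster : next_cluster + k]
        next_cluster += k
        base_tokens = [clusters[i][0] for i in own]
        label = " ".join(base_tokens).capitalize()
        synonyms = []
        for _ in range(rng.randint(*spec.synonyms_per_concept)):
            toks = [rng.choice(clusters[i]) for i in own]
            if len(toks) > 1 and rng.random() < 0.5:
                rng.shuffle(toks)
            if len(toks) > 1 and rng.random() < 0.4:
                pos = rng.randint(1, len(toks) - 1)
                toks = toks[:pos] + [rng.choice(_STOPWORDS_INSIDE)] + toks[pos:]
            syn = " ".join(toks)
            if syn.lower() != label.lower():
                synonyms.append(syn)
        concepts.append(
            Concept(
                concept_id=f"FX:{ci + 1:07d}",
                label=label,
                synonyms=synonyms,
                synonym_scopes=["EXACT"] * len(synonyms),
            )
        )
    # concept -> its cluster indices, replayed from the allocation above
    concept_clusters: dict[str, list[int]] = {}
    next_cluster = 0
    for c in concepts:
        k = len(c.label.split())
        concept_clusters[c.concept_id] = pool[next_cluster : next_cluster + k]
        next_cluster += k

    # obsolete concepts donate their ID as alt_id of a current replacement
    n_obsolete = int(round(spec.obsolete_fraction * spec.n_concepts))
    for oi in range(n_obsolete):
        target = concepts[rng.randrange(spec.n_concepts)]
        old_id = f"FX:{9000 + oi:07d}"
        target.alt_ids.append(old_id)
        concepts.append(
            Concept(
                concept_id=old_id,
                label=f"obsolete {target.label}",
                obsolete=True,
                replaced_by=target.concept_id,
            )
        )

    distractor_pool = [_make_stem(rng, taken) + "w" for _ in range(30)]

    documents: list[tuple[str, str]] = []
    gold: list[GoldAnnotation] = []
    ledger: list[tuple[str, int, int, str, str, bool]] = []
    current = [c for c in concepts if not c.obsolete]
    for di in range(spec.n_docs):
        doc_id = f"doc{di + 1:03d}"
        parts: list[str] = []
        pos = 0

        def emit(word: str) -> None:
            nonlocal pos
            if parts and not parts[-1].endswith(" "):
                parts.append(" ")
                pos += 1
            parts.append(word)
            pos += len(word)

        n_mentions = rng.randint(*spec.mentions_per_doc)
        for _ in range(n_mentions):
            # leading distractors, geometric at the requested rate (capped)
            for _ in range(8):
                if rng.random() >= spec.distractor_token_rate:
                    break
                emit(rng.choice(distractor_pool))
            concept = rng.choice(current)
            own = concept_clusters[concept.concept_id]
            toks = [rng.choice(clusters[i]) for i in own]
            if len(toks) > 1 and rng.random() < 0.3:
                rng.shuffle(toks)
            if len(toks) > 1 and rng.random() < 0.3:
                p = rng.randint(1, len(toks) - 1)
                toks = toks[:p] + [rng.choice(_STOPWORDS_INSIDE)] + toks[p:]
            recoverable = True
            if rng.random() < spec.unseen_variant_fraction:
                word_positions = [i for i, t in enumerate(toks) if t not in _STOPWORDS_INSIDE]
                wi = rng.choice(word_positions)
                toks[wi] = toks[wi] + "qx"  # variant absent from cluster file
                recoverable = False
            surface = " ".join(toks)
            if parts and not parts[-1].endswith(" "):
                parts.append(" ")
                pos += 1
            start = pos
            parts.append(surface)
            pos += len(surface)
            end = pos
            parts.append(".")  # sentence break isolates planted mentions
            pos += 1
            gold.append(GoldAnnotation(doc_id, concept.concept_id, start, end))
            ledger.append((doc_id, start, end, surface, concept.concept_id, recoverable))
        text = "".join(parts)
        documents.append((doc_id, text))

    return FixtureBundle(
        concepts=concepts,
        cluster_lines=cluster_lines,
        documents=documents,
        gold=gold,
        ledger=ledger,
    )
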