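"""Ontology parsing and the cluster-signature concept index.

Every label and synonym of every non-obsolete concept is turned into a
*signature*: the surface is tokenized, stop words are filtered out, each
remaining token is replaced by its cluster ID, and the set of IDs is
serialized as a single lexicographically sorted ``-``-joined key paired with
the filtered token count.  ``"Increased size of cranium"`` with the map
``{increased→C2, size→C26, cranium→C35}`` becomes ``("C2-C26-C35", 3)``.
The length disambiguates the rare surfaces in which the same cluster ID
occurs twice.

The final index stores strictly (a) the signature map — key+length to the
concepts and original surfaces it came from — and (b) a token map covering
the *entire* membership of every cluster that contributed a token (variant
closure: that is how morphological variants never seen in the ontology still
match), plus the blacklist.  Nothing else from the vocabulary is retained.

OBO files are read through :mod:`obonet`; obographs JSON is read directly.
"""

from __future__ import annotations

import datetime
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import obonet

from importlib import resources

from .cluster_vocab import ClusterVocabulary, normalize_spelling

__all__ = [
    "Concept",
    "Signature",
    "ConceptIndex",
    "IndexEntry",
    "parse_ontology",
    "tokenize_surface",
    "filter_blacklist",
    "consolidate",
    "make_signature",
    "build_index",
    "save_index",
    "load_index",
    "default_blacklist",
]

SCHEMA_VERSION = "1"

_TOKEN_RE = re.compile(r"[a-z0-9]+")
_SYNONYM_RE = re.compile(r'"(?P<text>(?:[^"\\]|\\.)*)"\s*(?P<scope>[A-Z_]*)')

EXACT_SCOPES = {"EXACT", ""}


@dataclass
class Concept:
    """One ontology concept: CURIE, label, synonyms, ID history."""

    concept_id: str
    label: Optional[str] = None
    synonyms: list[str] = field(default_factory=list)
    synonym_scopes: list[str] = field(default_factory=list)
    alt_ids: list[str] = field(default_factory=list)
    obsolete: bool = False
    replaced_by: Optional[str] = None

    def surfaces(self, exact_only: bool = False) -> list[tuple[str, bool]]:
        """(text, is_label) pairs to index for this concept."""
        out: list[tuple[str, bool]] = []
        if self.label:
            out.append((self.label, True))
        scopes = self.synonym_scopes or [""] * len(self.synonyms)
        for text, scope in zip(self.synonyms, scopes):
            if exact_only and scope not in EXACT_SCOPES:
                continue
            out.append((text, False))
        return out


def _parse_obo(path: str | Path) -> list[Concept]:
    graph = obonet.read_obo(str(path), ignore_obsolete=False)
    concepts = []
    for node_id, data in graph.nodes(data=True):
        synonyms, scopes = [], []
        for raw in data.get("synonym", []):
            m = _SYNONYM_RE.match(raw)
            if m:
                synonyms.append(m.group("text").replace('\\"', '"'))
                scopes.append(m.group("scope"))
        replaced = data.get("replaced_by", [])
        concepts.append(
            Concept(
                concept_id=node_id,
                label=data.get("name"),
                synonyms=synonyms,
                synonym_scopes=scopes,
                alt_ids=list(data.get("alt_id", [])),
                obsolete=str(data.get("is_obsolete", "false")).lower() == "true",
                replaced_by=replaced[0] if replaced else None,
            )
        )
    return concepts


def _curie(uri: str) -> str:
    # obographs nodes carry full IRIs: .../HP_0000256 -> HP:0000256
    tail = uri.rsplit("/", 1)[-1]
    return tail.replace("_", ":", 1) if "_" in tail and ":" not in tail else tail


def _parse_obographs(path: str | Path) -> list[Concept]:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    concepts = []
    for graph in doc.get("graphs", []):
        for node in graph.get("nodes", []):
            if node.get("type") not in (None, "CLASS"):
                continue
            meta = node.get("meta", {}) or {}
            synonyms, scopes = [], []
            for syn in meta.get("synonyms", []):
                val = syn.get("val")
                if val:
                    synonyms.append(val)
                    scopes.append((syn.get("pred") or "").replace("has", "").replace("Synonym", "").upper())
            alt_ids = [
                bp["val"]
                for bp in meta.get("basicPropertyValues", [])
                if bp.get("pred", "").endswith(("hasAlternativeId", "#hasAlternativeId"))
            ]
            replaced = [
                _curie(bp["val"])
                for bp in meta.get("basicPropertyValues", [])
                if bp.get("pred", "").endswith("term_replaced_by")
            ]
            concepts.append(
                Concept(
                    concept_id=_curie(node["id"]),
                    label=node.get("lbl"),
                    synonyms=synonyms,
                    synonym_scopes=scopes,
                    alt_ids=alt_ids,
                    obsolete=bool(meta.get("deprecated", False)),
                    replaced_by=replaced[0] if replaced else None,
                )
            )
    return concepts


def parse_ontology(path: str | Path, fmt: Optional[str] = None) -> list[Concept]:
    """Parse an OBO or obographs-JSON ontology into Concept records.

    Obsolete concepts are returned too (flagged, with ``replaced_by`` when
    present); callers that build the index skip them, while corpus alignment
    needs them.  ``fmt`` is inferred from the suffix when omitted.
    """
    path = Path(path)
    if fmt is None:
        fmt = "obographs-json" if path.suffix.lower() == ".json" else "obo"
    try:
        if fmt == "obo":
            return _parse_obo(path)
        if fmt == "obographs-json":
            return _parse_obographs(path)
    except (ValueError, KeyError, json.JSONDecodeError) as exc:
        raise ValueError(f"cannot parse ontology {path} as {fmt}: {exc}") from exc
    raise ValueError(f"unknown ontology format: {fmt}")


def tokenize_surface(text: str) -> list[str]:
    """Lowercase and split on any non-alphanumeric run; drop empty pieces."""
    return _TOKEN_RE.findall(text.lower())


def filter_blacklist(tokens: Sequence[str], blacklist: set[str]) -> list[str]:
    """Order-preserving removal of blacklisted tokens."""
    return [t for t in tokens if t not in blacklist]


@dataclass
class MissReport:
    """A surface that cannot be indexed: tokens with no cluster."""

    missing: list[str]


def consolidate(
    tokens: Sequence[str], vocab: ClusterVocabulary
) -> list[str] | MissReport:
    """Replace each token by its cluster ID.

    Letters-only tokens must be covered by the vocabulary; tokens containing
    digits get implicit singleton clusters keyed by their own text (the
    vocabulary only clusters proper words, but ontology surfaces such as
    "type 1" legitimately contain numerals).  If any letters-only token is
    uncovered the surface is reported unindexable with the offenders listed.
    """
    ids: list[str] = []
    missing: list[str] = []
    for tok in tokens:
        if tok.isalpha():
            cid = vocab.lookup(tok)
            if cid is None:
                missing.append(tok)
            else:
                ids.append(cid)
        else:
            ids.append(tok)
    if missing:
        return MissReport(missing)
    return ids


@dataclass(frozen=True)
class Signature:
    """Sorted unique cluster-ID key plus filtered token count."""

    key: str
    length: int


def make_signature(cluster_ids: Sequence[str]) -> Signature:
    """Serialize cluster IDs as ``sorted-unique-joined`` key + total length.

    ``[C3425, C112, C59] -> ("C112-C3425-C59", 3)``.  Plain string sort, so
    C112 precedes C59.  Length counts duplicates: ``[C7, C7] -> ("C7", 2)``.
    """
    if not cluster_ids:
        raise ValueError("empty surface after filtering")
    return Signature("-".join(sorted(set(cluster_ids))), len(cluster_ids))


@dataclass(frozen=True)
class IndexEntry:
    concept_id: str
    surface: str
    is_label: bool


@dataclass
class ConceptIndex:
    """The queryable artifact: token map + signature map + blacklist."""

    token_map: dict[str, str]
    signature_map: dict[tuple[str, int], list[IndexEntry]]
    blacklist: set[str]
    metadata: dict = field(default_factory=dict)
    # obsolete-ID side table for corpus alignment: old CURIE -> current CURIE
    alt_id_map: dict[str, str] = field(default_factory=dict)
    skipped_surfaces: list[tuple[str, str, list[str]]] = field(default_factory=list)
    n_indexed: int = 0

    def lookup_token(self, token: str) -> Optional[str]:
        return self.token_map.get(normalize_spelling(token))

    def lookup_signature(self, sig: Signature) -> list[IndexEntry]:
        return self.signature_map.get((sig.key, sig.length), [])


def default_blacklist() -> set[str]:
    text = resources.files("ontosig.data").joinpath("blacklist.txt").read_text("utf-8")
    return {
        line.strip().lower()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    }


def build_alt_id_map(concepts: Iterable[Concept]) -> dict[str, str]:
    """old CURIE -> current CURIE, via alt_id and obsolete/replaced_by.

    An alt_id claimed by two concepts is an error: the mapping would be
    ambiguous and corpus alignment non-deterministic.
    """
    owner: dict[str, str] = {}
    for c in concepts:
        if c.obsolete:
            continue
        for alt in c.alt_ids:
            if alt in owner and owner[alt] != c.concept_id:
                raise ValueError(
                    f"ambiguous alt_id {alt}: claimed by {owner[alt]} and {c.concept_id}"
                )
            owner[alt] = c.concept_id
    for c in concepts:
        if c.obsolete and c.replaced_by and c.concept_id not in owner:
            owner[c.concept_id] = c.replaced_by
    return owner


def build_index(
    concepts: Sequence[Concept],
    vocab: ClusterVocabulary,
    blacklist: Optional[set[str]] = None,
    exact_synonyms_only: bool = False,
    ontology_version: str = "",
) -> ConceptIndex:
    """Index every surface of every non-obsolete concept.

    Pipeline per surface: tokenize -> blacklist filter -> consolidate ->
    signature -> insert.  Surfaces empty after filtering, or containing
    uncovered letters-only tokens, are recorded in ``skipped_surfaces`` and
    left out.  The token map closes over full cluster memberships (variant
    closure), restricted to clusters actually used by some surface.
    """
    if blacklist is None:
        blacklist = default_blacklist()
    signature_map: dict[tuple[str, int], list[IndexEntry]] = {}
    used_clusters: set[str] = set()
    implicit_tokens: set[str] = set()
    skipped: list[tuple[str, str, list[str]]] = []
    n_indexed = 0

    for concept in concepts:
        if concept.obsolete:
            continue
        for text, is_label in concept.surfaces(exact_only=exact_synonyms_only):
            tokens = filter_blacklist(tokenize_surface(text), blacklist)
            if not tokens:
                skipped.append((concept.concept_id, text, []))
                continue
            ids = consolidate(tokens, vocab)
            if isinstance(ids, MissReport):
                skipped.append((concept.concept_id, text, ids.missing))
                continue
            sig = make_signature(ids)
            entry = IndexEntry(concept.concept_id, text, is_label)
            bucket = signature_map.setdefault((sig.key, sig.length), [])
            if entry not in bucket:
                bucket.append(entry)
            for cid in ids:
                # implicit singleton ids are the (lowercase) token text of a
                # digit-bearing token; real cluster ids are "C<n>"
                if cid.startswith("C") and cid[1:].isdigit():
                    used_clusters.add(cid)
                else:
                    implicit_tokens.add(cid)
            n_indexed += 1

    by_id = {c.cluster_id: c for c in vocab.clusters}
    token_map: dict[str, str] = {}
    for cid in used_clusters:
        for member in by_id[cid].members:
            token_map[normalize_spelling(member)] = cid
    for tok in implicit_tokens:
        token_map[tok] = tok

    metadata = {
        "ontology_version": ontology_version,
        "built": datetime.datetime.now(datetime.timezone.utc).strftime(
            "%Y-%m-%dT%H:%M:%SZ"
        ),
        "clusterer": "cluster-file",
        "n_concepts_indexed": len({e.concept_id for b in signature_map.values() for e in b}),
    }
    index = ConceptIndex(
        token_map=token_map,
        signature_map=signature_map,
        blacklist=set(blacklist),
        metadata=metadata,
        alt_id_map=build_alt_id_map(concepts),
        skipped_surfaces=skipped,
        n_indexed=n_indexed,
    )
    return index


def save_index(index: ConceptIndex, path: str | Path) -> None:
    """Write the index as a versioned JSON document (deterministic order)."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "metadata": index.metadata,
        "blacklist": sorted(index.blacklist),
        "token_map": dict(sorted(index.token_map.items())),
        "alt_id_map": dict(sorted(index.alt_id_map.items())),
        "signatures": [
            {
                "key": key,
                "length": length,
                "matches": [
                    {"id": e.concept_id, "surface": e.surface, "is_label": e.is_label}
                    for e in entries
                ],
            }
            for (key, length), entries in sorted(index.signature_map.items())
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1, sort_keys=False)
        fh.write("\n")


def load_index(path: str | Path) -> ConceptIndex:
    with open(path, encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"corrupt index file {path}: {exc}") from exc
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"index schema version mismatch: file has {version!r}, "
            f"this build reads {SCHEMA_VERSION!r}"
        )
    signature_map = {
        (s["key"], s["length"]): [
            IndexEntry(m["id"], m["surface"], m["is_label"]) for m in s["matches"]
        ]
        for s in doc["signatures"]
    }
    return ConceptIndex(
        token_map=doc["token_map"],
        signature_map=signature_map,
        blacklist=set(doc["blacklist"]),
        metadata=doc.get("metadata", {}),
        alt_id_map=doc.get("alt_id_map", {}),
    )
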