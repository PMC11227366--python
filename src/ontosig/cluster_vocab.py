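"""Clusters of morphologically equivalent tokens.

The whole recognition method rests on a *cluster vocabulary*: a strict
partition of a token set into groups of forms that should be treated as
interchangeable during matching (e.g. ``short / shorter / shorten /
shortening``).  Lemmatization is not sufficient for this — the lemma of
*shorter* is *short* while the lemma of *shortening* is *shorten* — so the
vocabulary is built by grouping tokens that share a 4-letter prefix and then
consolidating each prefix group by a canonical stem.  Localized spelling
variants (``haemorrhage`` / ``hemorrhage``) are folded together before
grouping so they land in the same prefix group despite differing raw
prefixes.

Cluster IDs are opaque ``"C<n>"`` strings; they carry no meaning beyond
identity within one vocabulary and are assigned deterministically
(``C1, C2, …`` in lexicographic order of each cluster's smallest member) so
that rebuilding from the same token set reproduces identical IDs.

Externally built clusterings are supported through a plain-text file format:
one cluster per line, members whitespace-separated, ``#`` comments ignored.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional

from ._stem import DEFAULT_STEMMER, STEMMERS

__all__ = [
    "Cluster",
    "ClusterVocabulary",
    "normalize_token",
    "normalize_spelling",
    "build_clusters",
    "load_clusters",
    "save_clusters",
    "cluster_of",
]

PREFIX_LEN = 4

# Ordered British->American substitutions; applied to a fixed point so the
# result is idempotent even on pathological inputs ("aaee").
_SPELLING_SUBS = (
    ("ae", "e"),
    ("oe", "e"),
)


def normalize_token(raw: str) -> Optional[str]:
    """Lowercase ``raw``; return None unless the result is letters-only.

    Only "proper words" (tokens formed of letters only) enter the cluster
    vocabulary; anything else is a miss, not an error.
    """
    low = raw.lower()
    if low and low.isalpha():
        return low
    return None


def normalize_spelling(token: str) -> str:
    """Collapse localized spellings onto one canonical (American) form.

    ``hypocalcaemia -> hypocalcemia``, ``haemorrhage -> hemorrhage``.
    Deterministic and idempotent (substitutions run to a fixed point).
    """
    word = token
    while True:
        prev = word
        for old, new in _SPELLING_SUBS:
            word = word.replace(old, new)
        if word == prev:
            return word


@dataclass(frozen=True)
class Cluster:
    cluster_id: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"cluster {self.cluster_id} has no members")


@dataclass
class ClusterVocabulary:
    """A strict partition of tokens into clusters, with an O(1) lookup map.

    ``token_to_cluster`` is keyed by the *spelling-normalized* form of each
    member, which is how spelling variants resolve to one cluster.
    """

    clusters: list[Cluster]
    token_to_cluster: dict[str, str] = field(init=False)

    def __post_init__(self) -> None:
        mapping: dict[str, str] = {}
        for cluster in self.clusters:
            for member in cluster.members:
                key = normalize_spelling(member)
                owner = mapping.get(key)
                if owner is not None and owner != cluster.cluster_id:
                    raise ValueError(f"partition violation: {member}")
                mapping[key] = cluster.cluster_id
        if not mapping:
            raise ValueError("empty vocabulary")
        self.token_to_cluster = mapping

    def __len__(self) -> int:
        return len(self.clusters)

    def lookup(self, token: str) -> Optional[str]:
        return self.token_to_cluster.get(normalize_spelling(token))


def cluster_of(vocab: ClusterVocabulary, token: str) -> Optional[str]:
    """Cluster ID of ``token`` (after spelling normalization), or None."""
    return vocab.lookup(token)


def build_clusters(
    vocab: Iterable[str],
    stemmer: Callable[[str], str] | str = DEFAULT_STEMMER,
) -> ClusterVocabulary:
    """Partition a set of normalized tokens into morphological clusters.

    Two tokens share a cluster iff, after spelling normalization, they share
    the same 4-letter prefix and the same canonical stem.  Tokens shorter
    than 4 letters are grouped by their full text.  The ``stemmer`` is a
    pluggable strategy (name from the registry or any ``str -> str``
    callable); the pinned default keeps results reproducible.
    """
    if isinstance(stemmer, str):
        stemmer = STEMMERS[stemmer]
    tokens = sorted(set(vocab))
    if not tokens:
        raise ValueError("empty vocabulary")

    groups: dict[tuple[str, str], set[str]] = {}
    for tok in tokens:
        canon = normalize_spelling(tok)
        if len(canon) < PREFIX_LEN:
            key = (canon, canon)
        else:
            key = (canon[:PREFIX_LEN], stemmer(canon))
        groups.setdefault(key, set()).add(tok)

    ordered = sorted(groups.values(), key=min)
    clusters = [
        Cluster(f"C{i}", frozenset(members))
        for i, members in enumerate(ordered, start=1)
    ]
    return ClusterVocabulary(clusters)


def load_clusters(path: str | Path | io.TextIOBase) -> ClusterVocabulary:
    """Read a cluster file: one cluster per line, members space-separated.

    IDs are ``"C" + 1-based line number`` (comment/blank lines keep their
    line numbers so IDs are stable under annotation of the file).  A token
    appearing on two lines violates the partition and is an error.
    """
    if isinstance(path, io.TextIOBase):
        lines = path.read().splitlines()
    else:
        lines = Path(path).read_text(encoding="utf-8").splitlines()
    clusters: list[Cluster] = []
    seen: dict[str, int] = {}
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        members = set()
        for raw in stripped.split():
            tok = normalize_token(raw)
            if tok is None:
                raise ValueError(
                    f"line {lineno}: {raw!r} is not a letters-only token"
                )
            canon = normalize_spelling(tok)
            if canon in seen and seen[canon] != lineno:
                raise ValueError(f"partition violation: {tok}")
            seen[canon] = lineno
            members.add(tok)
        clusters.append(Cluster(f"C{lineno}", frozenset(members)))
    if not clusters:
        raise ValueError("empty cluster file")
    return ClusterVocabulary(clusters)


def save_clusters(vocab: ClusterVocabulary, path: str | Path) -> None:
    """Write the cluster-file format ``load_clusters`` reads.

    Clusters are emitted in ID order, members sorted, so saving the same
    vocabulary twice produces byte-identical files.  IDs are renumbered by
    line position on reload; the induced partition is preserved exactly.
    """
    ordered = sorted(vocab.clusters, key=lambda c: min(c.members))
    with open(path, "w", encoding="utf-8") as fh:
        for cluster in ordered:
            fh.write(" ".join(sorted(cluster.members)) + "\n")
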