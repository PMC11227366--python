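"""Shared fixtures: worked-example cluster maps, mini-ontologies, and an
independent brute-force annotation oracle."""

from __future__ import annotations

import io
import re

import pytest

from ontosig import Concept, build_index
from ontosig.cluster_vocab import load_clusters


def cluster_file_with_lines(assignments: dict[int, str], total: int) -> str:
    """A cluster file whose line numbers (= cluster IDs) are forced.

    ``assignments`` maps line number -> space-separated members; other lines
    get inert filler singletons so that e.g. line 26 really yields C26.
    """
    lines = []
    for n in range(1, total + 1):
        if n in assignments:
            lines.append(assignments[n])
        else:
            lines.append(f"filler{chr(97 + n // 26)}{chr(97 + n % 26)}")
    return "\n".join(lines) + "\n"


@pytest.fixture
def cranium_vocab():
    """Vocabulary realizing the canonical map increased->C2, size->C26,
    cranium->C35, with morphological variants in each cluster."""
    text = cluster_file_with_lines(
        {2: "increase increased increasing", 26: "size sizes sized",
         35: "cranium crania", 3: "macrocephaly"},
        total=35,
    )
    return load_clusters(io.StringIO(text))


@pytest.fixture
def cranium_index(cranium_vocab):
    concepts = [
        Concept("HP:0000256", "Macrocephaly",
                ["Increased size of cranium"], ["EXACT"]),
    ]
    return build_index(concepts, cranium_vocab, ontology_version="test")


@pytest.fixture
def hernia_index():
    vocab = load_clusters(io.StringIO("hernia hernias\numbilical\n"))
    concepts = [
        Concept("HP:0100790", "Hernia"),
        Concept("HP:0001537", "Umbilical hernia"),
    ]
    return build_index(concepts, vocab)


# ---------------------------------------------------------------------------
# Brute-force oracle: enumerate EVERY contiguous token window, filter
# blacklist, form the cluster multiset, compare (set + length) against every
# indexed surface.  Independent of the candidate/decomposition machinery.
# ---------------------------------------------------------------------------

_WORD = re.compile(r"[a-z0-9]+")


def _spellnorm(tok: str) -> str:
    while True:
        new = tok.replace("ae", "e").replace("oe", "e")
        if new == tok:
            return new
        tok = new


def oracle_annotate(text: str, index, window_cap: int = 10) -> set[tuple[int, int, str]]:
    """All (start, end, concept_id) mentions by exhaustive window search."""
    low = text.lower()
    words = [(m.group(), m.start(), m.end()) for m in _WORD.finditer(low)]
    # punctuation (any non-space) in the gap after word i breaks continuity
    broken_after = []
    for i, (_, _, end) in enumerate(words):
        nxt = words[i + 1][1] if i + 1 < len(words) else len(text)
        broken_after.append(bool(low[end:nxt].strip()))
    mentions: set[tuple[int, int, str]] = set()
    for i in range(len(words)):
        for j in range(i, len(words)):
            if j > i and any(broken_after[k] for k in range(i, j)):
                continue
            kept = [w for w in words[i : j + 1] if w[0] not in index.blacklist]
            if not kept or len(kept) > window_cap:
                continue
            cids = []
            ok = True
            for tok, _, _ in kept:
                cid = index.token_map.get(
                    _spellnorm(tok) if tok.isalpha() else tok
                )
                if cid is None:
                    ok = False
                    break
                cids.append(cid)
            if not ok:
                continue
            key = "-".join(sorted(set(cids)))
            length = len(cids)
            span = (kept[0][1], kept[-1][2])
            for (sig_key, sig_len), entries in index.signature_map.items():
                if sig_key == key and sig_len == length:
                    for e in entries:
                        mentions.add((span[0], span[1], e.concept_id))
    return mentions
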