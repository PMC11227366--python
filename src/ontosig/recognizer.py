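"""Concept recognition: annotate free text against a ConceptIndex.

Instead of proposing entity boundaries first, the text itself is projected
into cluster-ID space: every token is looked up once in the index's token
map (one pass, O(tokens)).  Runs of in-index tokens — with stop words
transparent inside them, and unknown tokens or punctuation breaking them —
become *candidates*.  Each candidate is decomposed into all of its
contiguous windows so nested concepts are covered, and each window is a
single hash lookup: its cluster IDs as a sorted-unique signature key plus
the window length.  Matching is therefore order-insensitive inside a window
("short phalanx" and "phalanx shortening" hit the same signature) and linear
in the number of windows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from .cluster_vocab import normalize_spelling
from .ontology_index import ConceptIndex, Signature, make_signature, _TOKEN_RE

__all__ = [
    "TokenStatus",
    "DocToken",
    "Candidate",
    "Mention",
    "AnnotationStats",
    "tokenize_text",
    "label_tokens",
    "form_candidates",
    "decompose",
    "match",
    "annotate",
    "annotate_corpus",
    "write_mentions_tsv",
    "read_documents",
]

DEFAULT_WINDOW_CAP = 10

MENTION_TSV_HEADER = "# doc_id\tstart\tend\tsurface\tconcept_id\tmatched_term\tis_label (offsets 0-based, end-exclusive)"


class TokenStatus(str, Enum):
    KNOWN = "known"
    BLACKLISTED = "blacklisted"
    UNKNOWN = "unknown"
    BREAK = "punctuation-break"


@dataclass
class DocToken:
    text: str
    start: int
    end: int
    cluster_id: Optional[str] = None
    status: TokenStatus = TokenStatus.UNKNOWN


@dataclass
class Candidate:
    """Maximal run of known tokens (stop words transparent inside)."""

    cluster_seq: list[str]
    token_indices: list[int]
    span: tuple[int, int]


@dataclass(frozen=True)
class Mention:
    doc_id: str
    start: int
    end: int
    surface: str
    concept_id: str
    matched_term: str
    is_label: bool
    ambiguous: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotationStats:
    """Counters backing the linear-complexity contract."""

    n_tokens: int = 0
    n_token_lookups: int = 0
    n_candidates: int = 0
    n_signature_lookups: int = 0
    n_mentions: int = 0
    n_docs: int = 0

    def merge(self, other: "AnnotationStats") -> None:
        self.n_tokens += other.n_tokens
        self.n_token_lookups += other.n_token_lookups
        self.n_candidates += other.n_candidates
        self.n_signature_lookups += other.n_signature_lookups
        self.n_mentions += other.n_mentions
        self.n_docs += other.n_docs


def tokenize_text(text: str) -> list[DocToken]:
    """Split like surface tokenization but keep offsets and break markers.

    Word tokens are maximal alphanumeric runs (lowercased in ``.text``,
    offsets into the original string).  Any punctuation between, before, or
    after words emits one punctuation-break marker; whitespace alone does
    not break continuity.
    """
    tokens: list[DocToken] = []
    pos = 0
    for m in _TOKEN_RE.finditer(text.lower()):
        gap = text[pos : m.start()]
        if gap.strip():
            tokens.append(
                DocToken(gap.strip(), pos, m.start(), status=TokenStatus.BREAK)
            )
        tokens.append(DocToken(m.group(), m.start(), m.end()))
        pos = m.end()
    tail = text[pos:]
    if tail.strip():
        tokens.append(DocToken(tail.strip(), pos, len(text), status=TokenStatus.BREAK))
    return tokens


def label_tokens(
    tokens: Sequence[DocToken], index: ConceptIndex, stats: Optional[AnnotationStats] = None
) -> list[DocToken]:
    """Single pass over tokens: blacklist / token-map lookup, one per token."""
    for tok in tokens:
        if tok.status is TokenStatus.BREAK:
            continue
        if stats is not None:
            stats.n_token_lookups += 1
        if tok.text in index.blacklist:
            tok.status = TokenStatus.BLACKLISTED
            continue
        cid = index.token_map.get(normalize_spelling(tok.text)) if tok.text.isalpha() else index.token_map.get(tok.text)
        if cid is not None:
            tok.status = TokenStatus.KNOWN
            tok.cluster_id = cid
        else:
            tok.status = TokenStatus.UNKNOWN
    return list(tokens)


def form_candidates(tokens: Sequence[DocToken]) -> list[Candidate]:
    """Maximal known-token runs; stop words transparent, gaps terminate.

    Blacklisted tokens inside a run are skipped without breaking it, but
    cannot start or end one (indexed signatures exclude them).  Unknown
    tokens and punctuation breaks terminate the run.
    """
    candidates: list[Candidate] = []
    seq: list[str] = []
    idxs: list[int] = []

    def flush() -> None:
        nonlocal seq, idxs
        if seq:
            span = (tokens[idxs[0]].start, tokens[idxs[-1]].end)
            candidates.append(Candidate(seq, idxs, span))
        seq, idxs = [], []

    for i, tok in enumerate(tokens):
        if tok.status is TokenStatus.KNOWN:
            seq = seq + [tok.cluster_id] if seq else [tok.cluster_id]
            idxs = idxs + [i] if idxs else [i]
        elif tok.status is TokenStatus.BLACKLISTED:
            continue  # transparent
        else:  # unknown or punctuation break
            flush()
    flush()
    return candidates


def decompose(
    candidate: Candidate, window_cap: int = DEFAULT_WINDOW_CAP
) -> list[tuple[int, int]]:
    """All contiguous (i, j) windows of the candidate, longest first.

    The candidate itself plus every strictly shorter contiguous
    subsequence — left-to-right and right-to-left coverage of possibly
    nested concepts.  A length-k candidate yields k(k+1)/2 windows; windows
    longer than ``window_cap`` are not enumerated (term surfaces after stop
    word filtering are far shorter in practice).
    """
    k = len(candidate.cluster_seq)
    if k == 0:
        raise ValueError("empty candidate")
    windows = []
    for size in range(min(k, window_cap), 0, -1):
        for i in range(0, k - size + 1):
            windows.append((i, i + size))
    return windows


def match(
    cluster_window: Sequence[str], index: ConceptIndex
) -> list:
    """One signature lookup: sorted-unique key + window length."""
    sig = make_signature(list(cluster_window))
    return index.lookup_signature(sig)


def annotate(
    text: str,
    index: ConceptIndex,
    policy: str = "all",
    doc_id: str = "doc",
    window_cap: int = DEFAULT_WINDOW_CAP,
    stats: Optional[AnnotationStats] = None,
) -> list[Mention]:
    """Full pipeline: tokenize, label, form candidates, decompose, match.

    ``policy="all"`` returns every matched window, nested matches included;
    ``policy="longest-only"`` greedily keeps the longest non-overlapping
    mentions (ties broken leftmost).  Output sorted by (start, -length).
    Mentions from an ambiguous signature (one key+length shared by several
    concepts) are flagged.
    """
    if policy not in ("all", "longest-only"):
        raise ValueError(f"unknown policy: {policy}")
    own_stats = stats if stats is not None else AnnotationStats()
    tokens = tokenize_text(text)
    own_stats.n_tokens += sum(1 for t in tokens if t.status is not TokenStatus.BREAK)
    label_tokens(tokens, index, stats=own_stats)
    candidates = form_candidates(tokens)
    own_stats.n_candidates += len(candidates)

    found: dict[tuple[int, int, str], Mention] = {}
    for cand in candidates:
        for i, j in decompose(cand, window_cap=window_cap):
            own_stats.n_signature_lookups += 1
            entries = match(cand.cluster_seq[i:j], index)
            if not entries:
                continue
            first = tokens[cand.token_indices[i]]
            last = tokens[cand.token_indices[j - 1]]
            start, end = first.start, last.end
            for entry in entries:
                key = (start, end, entry.concept_id)
                if key not in found:
                    found[key] = Mention(
                        doc_id=doc_id,
                        start=start,
                        end=end,
                        surface=text[start:end],
                        concept_id=entry.concept_id,
                        matched_term=entry.surface,
                        is_label=entry.is_label,
                        ambiguous=len({e.concept_id for e in entries}) > 1,
                    )
    mentions = sorted(found.values(), key=lambda m: (m.start, -m.length, m.concept_id))
    if policy == "longest-only":
        mentions = _longest_only(mentions)
    own_stats.n_mentions += len(mentions)
    own_stats.n_docs += 1
    return mentions


def _longest_only(mentions: list[Mention]) -> list[Mention]:
    chosen: list[Mention] = []
    for m in sorted(mentions, key=lambda m: (-m.length, m.start, m.concept_id)):
        if all(m.end <= c.start or m.start >= c.end for c in chosen):
            chosen.append(m)
    return sorted(chosen, key=lambda m: (m.start, -m.length, m.concept_id))


def annotate_corpus(
    docs: Iterable[tuple[str, str]],
    index: ConceptIndex,
    policy: str = "all",
    window_cap: int = DEFAULT_WINDOW_CAP,
    stats: Optional[AnnotationStats] = None,
) -> Iterator[Mention]:
    """Stream mentions over (doc_id, text) pairs; constant memory in corpus.

    Unreadable documents are skipped and counted; counters accumulate into
    ``stats`` when given.
    """
    for doc_id, text in docs:
        if not isinstance(text, str):
            continue
        yield from annotate(
            text, index, policy=policy, doc_id=doc_id,
            window_cap=window_cap, stats=stats,
        )


def read_documents(path: str | Path) -> Iterator[tuple[str, str]]:
    """(doc_id, text) pairs from a JSONL file ({"id","text"} per line) or a
    directory of plain-text files (doc_id = file stem)."""
    path = Path(path)
    if path.is_dir():
        for fp in sorted(path.glob("*.txt")):
            yield fp.stem, fp.read_text(encoding="utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                rec = json.loads(line)
                yield str(rec["id"]), rec["text"]


def write_mentions_tsv(mentions: Iterable[Mention], path: str | Path) -> int:
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(MENTION_TSV_HEADER + "\n")
        for m in mentions:
            fh.write(
                f"{m.doc_id}\t{m.start}\t{m.end}\t{m.surface}\t{m.concept_id}"
                f"\t{m.matched_term}\t{str(m.is_label).lower()}\n"
            )
            n += 1
    return n
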