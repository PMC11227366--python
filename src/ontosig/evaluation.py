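"""Document- and mention-level scoring, and corpus/ontology ID alignment.

Document-level evaluation reduces gold and predictions to per-document sets
of concept IDs (boundary detection is disregarded); mention-level evaluation
scores each positioned mention, requiring span agreement under an exact or
overlap policy.  Counts are micro-averaged over documents by default
(tp/fp/fn summed, then P = tp/(tp+fp), R = tp/(tp+fn), F1 = 2PR/(P+R)); a
macro flag averages per-document scores instead.

Gold corpora annotated against an older ontology release routinely carry
retired concept IDs; ``align_corpus`` rewrites them to the current IDs via
the alt_id property (and replaced_by on obsolete terms), reporting what was
replaced, what was already current, and any orphans.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .ontology_index import Concept, ConceptIndex, build_alt_id_map
from .recognizer import Mention, AnnotationStats, annotate, read_documents

__all__ = [
    "GoldAnnotation",
    "EvalReport",
    "AlignmentReport",
    "align_corpus",
    "doc_level",
    "mention_level",
    "evaluate_run",
    "read_gold_tsv",
    "write_gold_tsv",
]


@dataclass(frozen=True)
class GoldAnnotation:
    doc_id: str
    concept_id: str
    start: Optional[int] = None
    end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start is not None and self.end is not None:
            if not (0 <= self.start < self.end):
                raise ValueError(f"bad offsets {self.start}..{self.end}")

    @property
    def has_span(self) -> bool:
        return self.start is not None and self.end is not None


@dataclass
class EvalReport:
    level: str
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float

    @classmethod
    def from_counts(cls, level: str, tp: int, fp: int, fn: int) -> "EvalReport":
        p = tp / (tp + fp) if tp + fp > 0 else 0.0
        r = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = 2 * p * r / (p + r) if p + r > 0 else 0.0
        return cls(level, tp, fp, fn, p, r, f1)


@dataclass
class AlignmentReport:
    replaced: list[tuple[str, str]] = field(default_factory=list)
    orphans: list[str] = field(default_factory=list)
    unchanged: int = 0


def align_corpus(
    gold: Sequence[GoldAnnotation], concepts: Sequence[Concept]
) -> tuple[list[GoldAnnotation], AlignmentReport]:
    """Rewrite retired concept IDs in a gold corpus to current ones.

    Current ID -> unchanged; found among a concept's alt_ids (or via
    replaced_by of an obsolete term) -> replaced; otherwise -> orphan
    (reported, dropped from the aligned set).  Deterministic; an alt_id
    claimed by two concepts raises.
    """
    current = {c.concept_id for c in concepts if not c.obsolete}
    alt_map = build_alt_id_map(concepts)
    aligned: list[GoldAnnotation] = []
    report = AlignmentReport()
    for ann in gold:
        if ann.concept_id in current:
            aligned.append(ann)
            report.unchanged += 1
        elif ann.concept_id in alt_map:
            new_id = alt_map[ann.concept_id]
            report.replaced.append((ann.concept_id, new_id))
            aligned.append(
                GoldAnnotation(ann.doc_id, new_id, ann.start, ann.end)
            )
        else:
            report.orphans.append(ann.concept_id)
    return aligned, report


def _group_ids(anns: Iterable) -> dict[str, set[str]]:
    by_doc: dict[str, set[str]] = {}
    for a in anns:
        by_doc.setdefault(a.doc_id, set()).add(a.concept_id)
    return by_doc


def doc_level(
    gold: Sequence[GoldAnnotation],
    predicted: Sequence[Mention],
    macro: bool = False,
) -> EvalReport:
    """Presence/absence of concept IDs per document; positions ignored."""
    g = _group_ids(gold)
    p = _group_ids(predicted)
    tp = fp = fn = 0
    per_doc = []
    for doc_id in sorted(set(g) | set(p)):
        gs, ps = g.get(doc_id, set()), p.get(doc_id, set())
        d_tp, d_fp, d_fn = len(gs & ps), len(ps - gs), len(gs - ps)
        tp, fp, fn = tp + d_tp, fp + d_fp, fn + d_fn
        per_doc.append(EvalReport.from_counts("document", d_tp, d_fp, d_fn))
    if macro:
        n = len(per_doc) or 1
        prec = sum(r.precision for r in per_doc) / n
        rec = sum(r.recall for r in per_doc) / n
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        rep = EvalReport("document", tp, fp, fn, prec, rec, f1)
        return rep
    return EvalReport.from_counts("document", tp, fp, fn)


def mention_level(
    gold: Sequence[GoldAnnotation],
    predicted: Sequence[Mention],
    span_policy: str = "exact",
) -> EvalReport:
    """Positioned mentions; a prediction is tp iff an unmatched gold mention
    has the same concept and, under ``exact``, identical offsets, or, under
    ``overlap``, at least one shared character.  One-to-one greedy matching
    in document order; leftovers are fp / fn."""
    if span_policy not in ("exact", "overlap"):
        raise ValueError(f"unknown span policy: {span_policy}")
    for ann in gold:
        if not ann.has_span:
            raise ValueError(
                "gold annotations lack offsets; use doc_level for this corpus"
            )
    by_doc_gold: dict[str, list[GoldAnnotation]] = {}
    for ann in gold:
        by_doc_gold.setdefault(ann.doc_id, []).append(ann)
    by_doc_pred: dict[str, list[Mention]] = {}
    for m in predicted:
        by_doc_pred.setdefault(m.doc_id, []).append(m)

    tp = fp = fn = 0
    for doc_id in sorted(set(by_doc_gold) | set(by_doc_pred)):
        g = sorted(by_doc_gold.get(doc_id, []), key=lambda a: (a.start, a.end))
        preds = sorted(by_doc_pred.get(doc_id, []), key=lambda m: (m.start, m.end))
        used = [False] * len(g)
        for m in preds:
            hit = None
            for gi, ann in enumerate(g):
                if used[gi] or ann.concept_id != m.concept_id:
                    continue
                if span_policy == "exact":
                    ok = ann.start == m.start and ann.end == m.end
                else:
                    ok = m.start < ann.end and ann.start < m.end
                if ok:
                    hit = gi
                    break
            if hit is None:
                fp += 1
            else:
                used[hit] = True
                tp += 1
        fn += used.count(False)
    return EvalReport.from_counts("mention", tp, fp, fn)


def evaluate_run(
    index: ConceptIndex,
    corpus: str | Path,
    gold_path: str | Path,
    level: str = "document",
    span_policy: str = "exact",
    policy: str = "all",
) -> tuple[EvalReport, pd.DataFrame]:
    """Annotate a corpus and score it against gold in one call.

    Returns the aggregate report plus a per-document breakdown.  Documents
    present in only one of corpus/gold are scored as usual for predictions
    vs gold (absent side contributes an empty set); IDs appearing in gold but
    with no document text are excluded with a warning column.
    """
    gold = read_gold_tsv(gold_path)
    docs = list(read_documents(corpus))
    doc_ids = {d for d, _ in docs}
    gold_ids = {a.doc_id for a in gold}
    missing_docs = sorted(gold_ids - doc_ids)
    gold = [a for a in gold if a.doc_id in doc_ids]

    stats = AnnotationStats()
    predicted: list[Mention] = []
    for doc_id, text in docs:
        predicted.extend(annotate(text, index, policy=policy, doc_id=doc_id, stats=stats))

    if level == "document":
        report = doc_level(gold, predicted)
    elif level == "mention":
        report = mention_level(gold, predicted, span_policy=span_policy)
    else:
        raise ValueError(f"unknown level: {level}")

    rows = []
    for doc_id in sorted(doc_ids):
        g = [a for a in gold if a.doc_id == doc_id]
        p = [m for m in predicted if m.doc_id == doc_id]
        if level == "document":
            r = doc_level(g, p)
        else:
            r = mention_level(g, p, span_policy=span_policy)
        rows.append(
            {"doc_id": doc_id, "tp": r.tp, "fp": r.fp, "fn": r.fn,
             "precision": r.precision, "recall": r.recall, "f1": r.f1}
        )
    table = pd.DataFrame(rows, columns=["doc_id", "tp", "fp", "fn", "precision", "recall", "f1"])
    table.attrs["missing_docs"] = missing_docs
    table.attrs["stats"] = stats
    return report, table


def read_gold_tsv(path: str | Path) -> list[GoldAnnotation]:
    """Gold TSV: doc_id, start, end, surface, concept_id ("-" = no offset)."""
    out: list[GoldAnnotation] = []
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            doc_id, start, end, _surface, concept_id = row[:5]
            s = None if start == "-" else int(start)
            e = None if end == "-" else int(end)
            out.append(GoldAnnotation(doc_id, concept_id, s, e))
    return out


def write_gold_tsv(
    annotations: Sequence[GoldAnnotation] | Sequence[Mention],
    path: str | Path,
    surfaces: Optional[dict] = None,
) -> None:
    """Write the same TSV format; recognizer output is directly scoreable."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# doc_id\tstart\tend\tsurface\tconcept_id\n")
        for a in annotations:
            start = a.start if a.start is not None else "-"
            end = a.end if a.end is not None else "-"
            surface = getattr(a, "surface", None) or (
                surfaces.get((a.doc_id, a.start, a.end), "-") if surfaces else "-"
            )
            fh.write(f"{a.doc_id}\t{start}\t{end}\t{surface}\t{a.concept_id}\n")
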