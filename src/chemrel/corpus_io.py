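"""Readers and writers for the ChemProt challenge TSV dialects.

The ChemProt distribution ships three unquoted, UTF-8, tab-separated files
per split: abstracts (pmid, title, abstract), entity mentions (pmid,
term id, type, start, end, surface text) and gold relations.  Character
offsets index into the concatenation of title and abstract; whether the
two are joined by a tab or a space varies between distributions, so the
join convention is resolved per document by validating that every
mention's surface text equals the corresponding character slice.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

EVALUATED_CPRS = ("CPR:3", "CPR:4", "CPR:5", "CPR:6", "CPR:9")
ALL_CPRS = tuple(f"CPR:{i}" for i in range(1, 11))
#: Fixed label order used everywhere downstream (label id 0..5).
LABELS = ("NA",) + EVALUATED_CPRS


class ParseError(ValueError):
    """A malformed line in one of the TSV dialects."""


class EntityType(str, Enum):
    CHEMICAL = "CHEMICAL"
    GENE = "GENE"


@dataclass(frozen=True)
class Document:
    """One PubMed abstract: the unit of the corpus."""

    pmid: str
    title: str
    abstract: str

    def text(self, sep: str = "\t") -> str:
        """Title and abstract as one string; offsets index into this."""
        return self.title + sep + self.abstract


@dataclass(frozen=True)
class EntityMention:
    """A chemical or gene/protein mention with character offsets.

    Offsets are 0-based, end-exclusive, over ``Document.text()``.
    """

    pmid: str
    term_id: str
    etype: EntityType
    start: int
    end: int
    text: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ParseError(
                f"{self.pmid}/{self.term_id}: invalid span [{self.start},{self.end})"
            )
        if len(self.text) != self.end - self.start:
            raise ParseError(
                f"{self.pmid}/{self.term_id}: text length {len(self.text)} "
                f"!= span length {self.end - self.start}"
            )


@dataclass(frozen=True)
class GoldRelation:
    """A gold-standard relation between a chemical and a gene mention."""

    pmid: str
    cpr: str
    arg1: str  # chemical term_id
    arg2: str  # gene term_id

    def __post_init__(self) -> None:
        if self.cpr not in ALL_CPRS:
            raise ParseError(f"{self.pmid}: unknown CPR token {self.cpr!r}")


@dataclass(frozen=True)
class PredictionRecord:
    """One predicted relation in the official submission format."""

    pmid: str
    cpr: str
    arg1: str
    arg2: str

    def __post_init__(self) -> None:
        if self.cpr not in EVALUATED_CPRS:
            raise ParseError(
                f"{self.pmid}: predictions may only contain the five evaluated "
                f"classes, got {self.cpr!r}"
            )


def _lines(path: str | Path) -> Iterable[tuple[int, str]]:
    with io.open(path, "r", encoding="utf-8", newline="") as fh:
        for lineno, raw in enumerate(fh.read().split("\n"), start=1):
            if raw == "":
                continue
            yield lineno, raw.rstrip("\r")


def read_abstracts(path: str | Path) -> list[Document]:
    """Read the abstracts TSV: ``pmid \\t title \\t abstract``.

    The abstract itself may contain no tabs (the format is unquoted), so a
    line with more than three fields is malformed.
    """
    docs = []
    for lineno, line in _lines(path):
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}: line {lineno}: expected 3 fields, got {len(parts)}")
        pmid, title, abstract = parts[0], parts[1], "\t".join(parts[2:])
        if not pmid:
            raise ParseError(f"{path}: line {lineno}: empty pmid")
        docs.append(Document(pmid=pmid, title=title, abstract=abstract))
    return docs


_TYPE_MAP = {
    "CHEMICAL": EntityType.CHEMICAL,
    "GENE": EntityType.GENE,
    "GENE-Y": EntityType.GENE,
    "GENE-N": EntityType.GENE,
}


def read_entities(path: str | Path) -> list[EntityMention]:
    """Read the entities TSV: pmid, term id, type, start, end, text.

    GENE-Y (normalizable) and GENE-N (non-normalizable) both map to GENE:
    the models treat all gene/protein mentions uniformly.
    """
    mentions = []
    for lineno, line in _lines(path):
        parts = line.split("\t")
        if len(parts) != 6:
            raise ParseError(f"{path}: line {lineno}: expected 6 fields, got {len(parts)}")
        pmid, term_id, etype_s, start_s, end_s, text = parts
        if etype_s not in _TYPE_MAP:
            raise ParseError(f"{path}: line {lineno}: unknown entity type {etype_s!r}")
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: non-integer offsets") from exc
        try:
            mentions.append(
                EntityMention(pmid, term_id, _TYPE_MAP[etype_s], start, end, text)
            )
        except ParseError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return mentions


def read_gold_relations(path: str | Path, dialect: str = "gold_standard") -> list[GoldRelation]:
    """Read gold relations in either challenge dialect.

    ``full``: 6 fields (pmid, CPR, eval-flag, CPR text, Arg1:Tx, Arg2:Ty);
    ``gold_standard``: 4 fields (pmid, CPR, Arg1:Tx, Arg2:Ty).  All ten CPR
    groups are retained on read; mapping the non-evaluated groups to NA is
    the instance-generation step's job.
    """
    if dialect not in ("full", "gold_standard"):
        raise ValueError(f"unknown dialect {dialect!r}")
    nfields = 6 if dialect == "full" else 4
    rels = []
    for lineno, line in _lines(path):
        parts = line.split("\t")
        if len(parts) != nfields:
            raise ParseError(
                f"{path}: line {lineno}: expected {nfields} fields "
                f"({dialect} dialect), got {len(parts)}"
            )
        pmid, cpr = parts[0], parts[1]
        arg1, arg2 = parts[-2], parts[-1]
        if not (arg1.startswith("Arg1:") and arg2.startswith("Arg2:")):
            raise ParseError(f"{path}: line {lineno}: missing Arg1:/Arg2: prefixes")
        try:
            rels.append(GoldRelation(pmid, cpr, arg1[5:], arg2[5:]))
        except ParseError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return rels


def write_predictions(records: Sequence[PredictionRecord], path: str | Path) -> None:
    """Write predictions in the official submission format.

    Lines are ``pmid \\t CPR:k \\t Arg1:Tx \\t Arg2:Ty``, deduplicated on the
    full tuple, NA never written (PredictionRecord cannot hold NA).
    """
    seen = set()
    with io.open(path, "w", encoding="utf-8", newline="") as fh:
        for rec in records:
            key = (rec.pmid, rec.cpr, rec.arg1, rec.arg2)
            if key in seen:
                continue
            seen.add(key)
            fh.write(f"{rec.pmid}\t{rec.cpr}\tArg1:{rec.arg1}\tArg2:{rec.arg2}\n")


def read_predictions(path: str | Path) -> list[PredictionRecord]:
    """Read a prediction file written by :func:`write_predictions`."""
    recs = []
    for lineno, line in _lines(path):
        parts = line.split("\t")
        if len(parts) != 4:
            raise ParseError(f"{path}: line {lineno}: expected 4 fields, got {len(parts)}")
        pmid, cpr, arg1, arg2 = parts
        if not (arg1.startswith("Arg1:") and arg2.startswith("Arg2:")):
            raise ParseError(f"{path}: line {lineno}: missing Arg1:/Arg2: prefixes")
        recs.append(PredictionRecord(pmid, cpr, arg1[5:], arg2[5:]))
    return recs


def resolve_join_separator(doc: Document, mentions: Sequence[EntityMention]) -> str:
    """Decide whether offsets assume tab or space between title and abstract.

    Returns the separator under which every mention's surface text equals
    the character slice of ``doc.text(sep)``; raises if neither works.
    """
    candidates = []
    for sep in ("\t", " "):
        text = doc.text(sep)
        if all(text[m.start : m.end] == m.text for m in mentions):
            candidates.append(sep)
    if not candidates:
        bad = next(
            m for m in mentions if doc.text("\t")[m.start : m.end] != m.text
        )
        raise ParseError(
            f"{doc.pmid}/{bad.term_id}: mention text {bad.text!r} does not match "
            f"the document slice under tab or space join"
        )
    return candidates[0]


def validate_relations(
    mentions: Sequence[EntityMention], relations: Sequence[GoldRelation]
) -> list[str]:
    """Check that every relation's arguments resolve to mentions of the
    correct type in the same document.  Returns human-readable problem
    descriptions; an empty list means the corpus is consistent."""
    by_key = {(m.pmid, m.term_id): m for m in mentions}
    problems = []
    for rel in relations:
        chem = by_key.get((rel.pmid, rel.arg1))
        gene = by_key.get((rel.pmid, rel.arg2))
        if chem is None:
            problems.append(f"{rel.pmid}: arg1 {rel.arg1} has no mention")
        elif chem.etype is not EntityType.CHEMICAL:
            problems.append(f"{rel.pmid}: arg1 {rel.arg1} is not a CHEMICAL")
        if gene is None:
            problems.append(f"{rel.pmid}: arg2 {rel.arg2} has no mention")
        elif gene.etype is not EntityType.GENE:
            problems.append(f"{rel.pmid}: arg2 {rel.arg2} is not a GENE")
    return problems


@dataclass
class CorpusStats:
    n_docs: int
    avg_entities_per_doc: float
    n_positive_relations: int
    n_instances: int
    instances_per_label: dict = field(default_factory=dict)


def corpus_stats(docs, mentions, instances) -> CorpusStats:
    """Summary statistics in the shape of the standard corpus-statistics
    table: document count, mean entities per document, positive relation
    count and total candidate-instance count."""
    n_docs = len(docs)
    avg = len(mentions) / n_docs if n_docs else 0.0
    per_label = Counter(inst.label for inst in instances)
    n_pos = sum(c for lab, c in per_label.items() if lab != "NA")
    return CorpusStats(
        n_docs=n_docs,
        avg_entities_per_doc=avg,
        n_positive_relations=n_pos,
        n_instances=len(instances),
        instances_per_label=dict(per_label),
    )
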