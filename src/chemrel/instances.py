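"""Sentence segmentation, entity alignment and relation-instance generation.

A relation instance is one (chemical mention, gene mention) pair that
co-occurs in a sentence, labeled with one of the five evaluated relation
groups (CPR:3/4/5/6/9) or NA.  Gold relations of the non-evaluated groups
(CPR 1, 2, 7, 8, 10) count as negatives, i.e. label NA.  Entity mentions
are blinded: every mention collapses to the single lowercase token
"chemical" or "gene", which removes the out-of-vocabulary problem for
entity names and gives each entity exactly one position index.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

from .corpus_io import (
    Document,
    EntityMention,
    EntityType,
    GoldRelation,
    LABELS,
    resolve_join_separator,
)

logger = logging.getLogger(__name__)

EVALUATED = set(LABELS[1:])

CHEM_TOKEN = "chemical"
GENE_TOKEN = "gene"

# Segmenter contract: text -> list of (start, end) sentence spans covering
# the text without overlap.  Any callable with this signature can be
# plugged in (e.g. a statistical segmenter); the default is rule-based.
Segmenter = Callable[[str], list[tuple[int, int]]]

_BOUNDARY = re.compile(r"[.?!]+[\)\]\"']*\s+(?=[A-Z0-9])")


def default_segmenter(text: str) -> list[tuple[int, int]]:
    """Split after sentence-final punctuation followed by whitespace and an
    uppercase letter or digit.  Deterministic, no trained models."""
    spans = []
    start = 0
    for m in _BOUNDARY.finditer(text):
        spans.append((start, m.end()))
        start = m.end()
    if start < len(text):
        spans.append((start, len(text)))
    # trim trailing/leading whitespace from each span
    out = []
    for s, e in spans:
        while s < e and text[s].isspace():
            s += 1
        while e > s and text[e - 1].isspace():
            e -= 1
        if s < e:
            out.append((s, e))
    return out


# Tokens are either alphanumeric compounds (hyphens/periods/slashes allowed
# inside, so "UCCB01-125" and "p38.2" survive) or single punctuation marks.
_TOKEN = re.compile(r"[A-Za-z0-9](?:[A-Za-z0-9._/+-]*[A-Za-z0-9])?|\S")


def tokenize(text: str, base: int = 0) -> list[tuple[str, tuple[int, int]]]:
    """Rule-based tokenizer: whitespace split with leading/trailing
    punctuation detached.  Returns (surface, (start, end)) with offsets
    shifted by ``base``."""
    return [
        (m.group(0), (base + m.start(), base + m.end()))
        for m in _TOKEN.finditer(text)
    ]


@dataclass
class Sentence:
    """One sentence with its tokens and the entity mentions inside it."""

    pmid: str
    start: int
    end: int
    tokens: list[tuple[str, tuple[int, int]]]
    mentions: list[EntityMention] = field(default_factory=list)

    @property
    def chemicals(self) -> list[EntityMention]:
        return [m for m in self.mentions if m.etype is EntityType.CHEMICAL]

    @property
    def genes(self) -> list[EntityMention]:
        return [m for m in self.mentions if m.etype is EntityType.GENE]


@dataclass
class RelationInstance:
    pmid: str
    sentence: Sentence
    chem: EntityMention
    gene: EntityMention
    label: str
    blinded_tokens: list[str]
    chem_token_pos: int
    gene_token_pos: int


def segment_sentences(
    doc: Document, segmenter: Segmenter = default_segmenter, sep: str = "\t"
) -> list[Sentence]:
    """Segment a document; the title is always the first sentence and is
    never merged into the abstract flow."""
    text = doc.text(sep)
    title_end = len(doc.title)
    sentences: list[Sentence] = []
    if doc.title:
        sentences.append(
            Sentence(doc.pmid, 0, title_end, tokenize(doc.title, base=0))
        )
    abs_base = title_end + len(sep)
    for s, e in segmenter(doc.abstract):
        sentences.append(
            Sentence(
                doc.pmid,
                abs_base + s,
                abs_base + e,
                tokenize(doc.abstract[s:e], base=abs_base + s),
            )
        )
    return sentences


def align_entities(
    sentences: list[Sentence], mentions: Sequence[EntityMention], doc_len: int
) -> list[Sentence]:
    """Attach each mention to the sentence containing it.

    A mention straddling a sentence boundary (a segmentation error) forces
    the two sentences to be merged rather than the mention dropped:
    deleting mentions silently deletes gold pairs and caps recall.
    """
    sentences = [replace(s, mentions=list(s.mentions)) for s in sentences]
    for m in sorted(mentions, key=lambda m: (m.start, m.end)):
        if m.end > doc_len:
            raise ValueError(
                f"{m.pmid}/{m.term_id}: mention end {m.end} outside document "
                f"of length {doc_len}"
            )
        covering = [
            i for i, s in enumerate(sentences) if m.start < s.end and m.end > s.start
        ]
        if not covering:
            # mention falls entirely in inter-sentence whitespace/separator;
            # attach to the nearest following sentence
            after = [i for i, s in enumerate(sentences) if s.start >= m.end]
            if not after:
                raise ValueError(f"{m.pmid}/{m.term_id}: cannot place mention")
            covering = [after[0]]
        first, last = covering[0], covering[-1]
        if last > first:
            merged = _merge_span(sentences[first : last + 1])
            sentences[first : last + 1] = [merged]
        sentences[first].mentions.append(m)
    return sentences


def _merge_span(span: list[Sentence]) -> Sentence:
    tokens = [t for s in span for t in s.tokens]
    mentions = [m for s in span for m in s.mentions]
    return Sentence(span[0].pmid, span[0].start, span[-1].end, tokens, mentions)


def enumerate_candidates(
    sentence: Sentence,
) -> list[tuple[EntityMention, EntityMention]]:
    """All chemical x gene pairs in the sentence, ordered by (chem offset,
    gene offset)."""
    chems = sorted(sentence.chemicals, key=lambda m: (m.start, m.end))
    genes = sorted(sentence.genes, key=lambda m: (m.start, m.end))
    return [(c, g) for c in chems for g in genes]


GoldIndex = dict[tuple[str, str, str], list[str]]


def index_gold(relations: Sequence[GoldRelation]) -> GoldIndex:
    idx: GoldIndex = {}
    for r in relations:
        idx.setdefault((r.pmid, r.arg1, r.arg2), []).append(r.cpr)
    return idx


def assign_label(
    pair: tuple[EntityMention, EntityMention], gold: GoldIndex
) -> str:
    """Label a candidate pair from the gold index.

    Evaluated groups keep their label; non-evaluated groups and unannotated
    pairs are NA.  If one pair carries several evaluated groups, the lowest
    CPR number wins and a warning is logged.
    """
    chem, gene = pair
    cprs = gold.get((chem.pmid, chem.term_id, gene.term_id), [])
    evaluated = sorted(
        (c for c in cprs if c in EVALUATED), key=lambda c: int(c.split(":")[1])
    )
    if not evaluated:
        return "NA"
    if len(set(evaluated)) > 1:
        logger.warning(
            "%s: pair (%s,%s) has multiple gold labels %s; keeping %s",
            chem.pmid, chem.term_id, gene.term_id, sorted(set(cprs)), evaluated[0],
        )
    return evaluated[0]


def blind_tokens(
    sentence: Sentence, pair: tuple[EntityMention, EntityMention]
) -> tuple[list[str], int, int]:
    """Replace every entity mention in the sentence by its type token.

    All mentions are blinded, not only the candidate pair, and a multi-word
    mention collapses to a single token, so each entity occupies exactly one
    position.  Non-entity tokens are lowercased.  Returns the blinded token
    list and the token indices of the pair's own chemical and gene tokens.
    """
    chem, gene = pair
    # map each token to the mention covering it (first match wins; mentions
    # are non-overlapping in well-formed corpora)
    spans = sorted(sentence.mentions, key=lambda m: (m.start, m.end))
    out: list[str] = []
    chem_pos = gene_pos = -1
    current: EntityMention | None = None
    for surface, (ts, te) in sentence.tokens:
        covering = next((m for m in spans if ts < m.end and te > m.start), None)
        if covering is not None:
            if covering is current:
                continue  # additional token of a multi-word mention
            current = covering
            out.append(
                CHEM_TOKEN if covering.etype is EntityType.CHEMICAL else GENE_TOKEN
            )
            if covering is chem:
                chem_pos = len(out) - 1
            elif covering is gene:
                gene_pos = len(out) - 1
        else:
            current = None
            out.append(surface.lower())
    if chem_pos < 0 or gene_pos < 0:
        raise ValueError(
            f"{sentence.pmid}: pair mentions not inside sentence "
            f"[{sentence.start},{sentence.end})"
        )
    return out, chem_pos, gene_pos


def build_instances(
    doc: Document,
    mentions: Sequence[EntityMention],
    gold: Sequence[GoldRelation] | GoldIndex,
    segmenter: Segmenter = default_segmenter,
) -> list[RelationInstance]:
    """Full per-document pipeline: segment, align, enumerate, label, blind.

    The instance count equals the sum over sentences of
    (#chemical mentions) x (#gene mentions).
    """
    doc_mentions = [m for m in mentions if m.pmid == doc.pmid]
    sep = resolve_join_separator(doc, doc_mentions) if doc_mentions else "\t"
    sentences = segment_sentences(doc, segmenter, sep=sep)
    sentences = align_entities(sentences, doc_mentions, len(doc.text(sep)))
    gold_idx = gold if isinstance(gold, dict) else index_gold(gold)
    instances = []
    for sent in sentences:
        for chem, gene in enumerate_candidates(sent):
            blinded, cpos, gpos = blind_tokens(sent, (chem, gene))
            instances.append(
                RelationInstance(
                    pmid=doc.pmid,
                    sentence=sent,
                    chem=chem,
                    gene=gene,
                    label=assign_label((chem, gene), gold_idx),
                    blinded_tokens=blinded,
                    chem_token_pos=cpos,
                    gene_token_pos=gpos,
                )
            )
    return instances


def unreachable_gold(
    instances: Sequence[RelationInstance], gold: Sequence[GoldRelation]
) -> list[GoldRelation]:
    """Gold relations of evaluated groups whose arguments never co-occur in
    one sentence.  These cannot be predicted by a same-sentence system and
    become false negatives at evaluation; they are reported, never dropped
    silently."""
    reachable = {(i.pmid, i.chem.term_id, i.gene.term_id) for i in instances}
    return [
        r
        for r in gold
        if r.cpr in EVALUATED and (r.pmid, r.arg1, r.arg2) not in reachable
    ]
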