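"""Synthetic ChemProt-format corpora with planted, known structure.

The generator emits abstracts/entities/gold-relations files in exactly the
challenge TSV dialects, with one class-specific trigger word planted next
to each positive chemical-gene pair (e.g. "inhibitor" for the
downregulator class CPR:4, "agonist" for CPR:5).  Negative (NA) sentences
contain a co-occurring chemical and gene with either no trigger at all or a
distractor trigger placed far from both entities.  A configurable fraction
of sentences carries a second, unrelated entity pair, which produces
multiple candidate instances per sentence — the regime where same-sentence
relation classifiers are known to struggle.

Because every planted relation is same-sentence by construction, the
tuple-evaluation recall ceiling on synthetic data is exactly 1.0, and the
truth table returned with the corpus is the ground truth the rest of the
pipeline must reproduce.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus_io import Document, EntityMention, EntityType, GoldRelation

#: Trigger lexicons per relation class: words of the kind that dominate the
#: max-attention tallies for each class (upregulation vocabulary for CPR:3,
#: inhibition for CPR:4, agonism for CPR:5, antagonism for CPR:6,
#: substrate/transport for CPR:9).  Disjoint across classes by design.
DEFAULT_TRIGGERS: dict[str, tuple[str, ...]] = {
    "CPR:3": ("expression", "phosphorylation", "activation"),
    "CPR:4": ("inhibitor", "inhibition", "inhibits"),
    "CPR:5": ("agonist", "agonists"),
    "CPR:6": ("antagonist", "antagonists"),
    "CPR:9": ("substrate", "transporter", "catalyzes"),
}

DEFAULT_CLASS_MIX: dict[str, float] = {
    "CPR:3": 0.15, "CPR:4": 0.15, "CPR:5": 0.15,
    "CPR:6": 0.15, "CPR:9": 0.15, "NA": 0.25,
}

#: Non-evaluated gold groups occasionally attached to NA pairs, exercising
#: the down-mapping of CPR 1/2/7/8/10 to NA.
NEGATIVE_GOLD_GROUPS = ("CPR:1", "CPR:2", "CPR:7", "CPR:8", "CPR:10")


@dataclass
class SynthConfig:
    n_docs: int = 1000
    sentences_per_doc: tuple[int, int] = (3, 4)  # inclusive range
    class_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    trigger_lexicons: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_TRIGGERS)
    )
    filler_vocab_size: int = 120
    multi_entity_frac: float = 0.25  # sentences with a second, unrelated pair
    distractor_frac: float = 0.20  # NA sentences with a far-away trigger
    negative_gold_frac: float = 0.20  # NA pairs given a non-evaluated gold group
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9 or any(v < 0 for v in self.class_mix.values()):
            raise ValueError(f"class_mix must be a probability simplex, sums to {total}")
        seen: set[str] = set()
        for words in self.trigger_lexicons.values():
            overlap = seen & set(words)
            if overlap:
                raise ValueError(f"trigger lexicons overlap on {sorted(overlap)}")
            seen |= set(words)


@dataclass
class TruthRow:
    pmid: str
    chem_tid: str
    gene_tid: str
    label: str
    trigger: str | None


@dataclass
class SynthCorpus:
    documents: list[Document]
    mentions: list[EntityMention]
    relations: list[GoldRelation]
    truth: list[TruthRow]
    config: SynthConfig

    def docs_subset(self, pmids: set[str]) -> "SynthCorpus":
        return SynthCorpus(
            documents=[d for d in self.documents if d.pmid in pmids],
            mentions=[m for m in self.mentions if m.pmid in pmids],
            relations=[r for r in self.relations if r.pmid in pmids],
            truth=[t for t in self.truth if t.pmid in pmids],
            config=self.config,
        )


def _filler_vocab(rng: np.random.Generator, size: int, reserved: set[str]) -> list[str]:
    syllables = ["ba", "co", "di", "fu", "ge", "ka", "lo", "mi", "na", "po",
                 "ra", "se", "ti", "vu", "we", "zo", "plex", "tran", "mod", "cy"]
    vocab: list[str] = []
    seen = set(reserved)
    while len(vocab) < size:
        n = rng.integers(2, 4)
        word = "".join(rng.choice(syllables) for _ in range(n))
        if word not in seen:
            seen.add(word)
            vocab.append(word)
    return vocab


def _entity_name(rng: np.random.Generator, kind: str, counter: int) -> str:
    letters = "".join(rng.choice(list(string.ascii_uppercase)) for _ in range(3))
    digits = rng.integers(10, 100)
    if kind == "chem":
        return f"{letters}{counter}-{digits}"
    return f"{letters}-{digits}"


def _pick(rng: np.random.Generator, seq: Sequence[str], n: int) -> list[str]:
    return [seq[int(i)] for i in rng.integers(0, len(seq), size=n)]


class _SentenceBuilder:
    """Accumulates one sentence's words, recording entity spans relative to
    the sentence start."""

    def __init__(self) -> None:
        self.words: list[str] = []
        self.entities: list[tuple[int, str, str]] = []  # (word idx, kind, name)

    def add(self, *words: str) -> None:
        self.words.extend(words)

    def add_entity(self, kind: str, name: str) -> None:
        self.entities.append((len(self.words), kind, name))
        self.words.append(name)

    def text(self) -> str:
        # capitalize the first character so the rule-based segmenter can see
        # the sentence boundary; entity names are already uppercase
        words = [self.words[0][0].upper() + self.words[0][1:]] + self.words[1:]
        return " ".join(words) + " ."


# Scaffolding pools shared verbatim by positive and negative templates, so
# no scaffold word carries class information: the planted trigger (or, in NA
# sentences, a random filler word in the same slot) is the only token that
# separates the classes.
_VERBS = ("is", "remains", "represents", "constitutes")
_ADJS = ("potent", "selective", "weak", "novel", "partial")
_PREPS = ("of", "for", "at", "on", "against")


def _keyword_sentence(rng, fillers, chem, gene, keyword: str) -> _SentenceBuilder:
    """One sentence with ``keyword`` in the relation slot between the two
    entities; identical scaffolding regardless of whether the keyword is a
    class trigger or an uninformative filler word."""
    b = _SentenceBuilder()
    verb = str(rng.choice(_VERBS))
    adj = str(rng.choice(_ADJS))
    prep = str(rng.choice(_PREPS))
    variant = int(rng.integers(0, 3))
    if variant == 0:
        b.add_entity("chem", chem)
        b.add(verb, "a", adj, keyword, prep)
        b.add_entity("gene", gene)
        b.add(*_pick(rng, fillers, int(rng.integers(2, 7))))
    elif variant == 1:
        b.add("treatment", "with")
        b.add_entity("chem", chem)
        b.add("resulted", "in", adj, keyword, prep)
        b.add_entity("gene", gene)
        b.add("in", *_pick(rng, fillers, int(rng.integers(2, 5))), "assays")
    else:
        b.add(*_pick(rng, fillers, int(rng.integers(1, 4))), "data", "showed", "that")
        b.add_entity("chem", chem)
        b.add("acts", "as", "a", keyword, prep)
        b.add_entity("gene", gene)
        b.add(*_pick(rng, fillers, int(rng.integers(2, 6))))
    return b


def _positive_sentence(rng, cfg, label, fillers, chem, gene) -> tuple[_SentenceBuilder, str]:
    trigger = str(rng.choice(cfg.trigger_lexicons[label]))
    return _keyword_sentence(rng, fillers, chem, gene, trigger), trigger


def _negative_sentence(rng, cfg, fillers, chem, gene, all_triggers) -> tuple[_SentenceBuilder, str | None]:
    filler_keyword = str(rng.choice(fillers))
    b = _keyword_sentence(rng, fillers, chem, gene, filler_keyword)
    distractor: str | None = None
    if rng.random() < cfg.distractor_frac:
        # the trigger appears, but syntactically detached and far from both
        # entities, so trigger presence alone is not a sufficient signal
        distractor = str(rng.choice(all_triggers))
        b.add(",", "whereas", distractor, "activity", "remained",
              *_pick(rng, fillers, int(rng.integers(1, 3))))
    return b, distractor


def generate(cfg: SynthConfig, out_dir: str | Path | None = None) -> SynthCorpus:
    """Generate a corpus; deterministic under ``cfg.seed``.

    When ``out_dir`` is given, writes ``abstracts.tsv``, ``entities.tsv``
    and ``relations.tsv`` (gold_standard dialect) there.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    labels = sorted(cfg.class_mix)
    probs = np.array([cfg.class_mix[k] for k in labels])
    all_triggers = [w for ws in cfg.trigger_lexicons.values() for w in ws]
    fillers = _filler_vocab(rng, cfg.filler_vocab_size, set(all_triggers))

    documents: list[Document] = []
    mentions: list[EntityMention] = []
    relations: list[GoldRelation] = []
    truth: list[TruthRow] = []

    lo, hi = cfg.sentences_per_doc
    for d in range(cfg.n_docs):
        pmid = str(10000 + d)
        title_words = _pick(rng, fillers, int(rng.integers(3, 6)))
        title = (" ".join(title_words) + " profiling study .").capitalize()
        sent_builders: list[tuple[_SentenceBuilder, str, str | None]] = []
        n_sent = int(rng.integers(lo, hi + 1))
        ent_counter = 0
        for _ in range(n_sent):
            label = str(rng.choice(labels, p=probs))
            ent_counter += 1
            chem = _entity_name(rng, "chem", ent_counter)
            ent_counter += 1
            gene = _entity_name(rng, "gene", ent_counter)
            if label == "NA":
                b, _ = _negative_sentence(rng, cfg, fillers, chem, gene, all_triggers)
                trig = None
            else:
                b, trig = _positive_sentence(rng, cfg, label, fillers, chem, gene)
            if rng.random() < cfg.multi_entity_frac:
                ent_counter += 1
                chem2 = _entity_name(rng, "chem", ent_counter)
                ent_counter += 1
                gene2 = _entity_name(rng, "gene", ent_counter)
                b.add(",", "and")
                b.add_entity("chem", chem2)
                b.add("was", "profiled", "alongside")
                b.add_entity("gene", gene2)
            sent_builders.append((b, label, trig))

        # lay out the abstract and convert word indices to char offsets over
        # the document text title + "\t" + abstract
        abstract_parts: list[str] = []
        doc_entities: list[tuple[str, str, int, int, str]] = []  # tid, kind, start, end, name
        tid_counter = 0
        base = len(title) + 1  # after the tab
        cursor = 0
        sentence_pairs: list[tuple[str, str | None, list[tuple[str, str]]]] = []
        for b, label, trig in sent_builders:
            text = b.text()
            word_offsets = []
            pos = 0
            for w in b.words + ["."]:
                word_offsets.append(pos)
                pos += len(w) + 1
            ents_here: list[tuple[str, str]] = []  # (tid, kind)
            for widx, kind, name in b.entities:
                tid_counter += 1
                tid = f"T{tid_counter}"
                start = base + cursor + word_offsets[widx]
                doc_entities.append((tid, kind, start, start + len(name), name))
                ents_here.append((tid, kind))
            sentence_pairs.append((label, trig, ents_here))
            abstract_parts.append(text)
            cursor += len(text) + 1  # sentences joined by single space
        abstract = " ".join(abstract_parts)
        documents.append(Document(pmid=pmid, title=title, abstract=abstract))
        for tid, kind, start, end, name in doc_entities:
            mentions.append(
                EntityMention(
                    pmid=pmid,
                    term_id=tid,
                    etype=EntityType.CHEMICAL if kind == "chem" else EntityType.GENE,
                    start=start,
                    end=end,
                    text=name,
                )
            )
        for label, trig, ents_here in sentence_pairs:
            chems = [t for t, k in ents_here if k == "chem"]
            genes = [t for t, k in ents_here if k == "gene"]
            primary_pair = (chems[0], genes[0])
            for ci, c in enumerate(chems):
                for gi, g in enumerate(genes):
                    if (c, g) == primary_pair and label != "NA":
                        relations.append(GoldRelation(pmid, label, c, g))
                        truth.append(TruthRow(pmid, c, g, label, trig))
                    else:
                        if rng.random() < cfg.negative_gold_frac:
                            grp = str(rng.choice(NEGATIVE_GOLD_GROUPS))
                            relations.append(GoldRelation(pmid, grp, c, g))
                        truth.append(TruthRow(pmid, c, g, "NA", None))

    corpus = SynthCorpus(documents, mentions, relations, truth, cfg)
    if out_dir is not None:
        write_corpus(corpus, out_dir)
    return corpus


def write_corpus(corpus: SynthCorpus, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "abstracts": out / "abstracts.tsv",
        "entities": out / "entities.tsv",
        "relations": out / "relations.tsv",
    }
    with open(paths["abstracts"], "w", encoding="utf-8") as fh:
        for d in corpus.documents:
            fh.write(f"{d.pmid}\t{d.title}\t{d.abstract}\n")
    with open(paths["entities"], "w", encoding="utf-8") as fh:
        for m in corpus.mentions:
            fh.write(
                f"{m.pmid}\t{m.term_id}\t{m.etype.value}\t{m.start}\t{m.end}\t{m.text}\n"
            )
    with open(paths["relations"], "w", encoding="utf-8") as fh:
        for r in corpus.relations:
            fh.write(f"{r.pmid}\t{r.cpr}\tArg1:{r.arg1}\tArg2:{r.arg2}\n")
    return paths


def split(
    corpus: SynthCorpus,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> tuple[SynthCorpus, SynthCorpus, SynthCorpus]:
    """Document-level train/dev/test partition: no sentence ever appears in
    two splits.  Deterministic under ``seed``."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    pmids = [d.pmid for d in corpus.documents]
    order = rng.permutation(len(pmids))
    n = len(pmids)
    n_train = int(round(fractions[0] * n))
    n_dev = int(round(fractions[1] * n))
    idx_train = {pmids[i] for i in order[:n_train]}
    idx_dev = {pmids[i] for i in order[n_train : n_train + n_dev]}
    idx_test = {pmids[i] for i in order[n_train + n_dev :]}
    parts = tuple(corpus.docs_subset(s) for s in (idx_train, idx_dev, idx_test))
    if any(not p.documents for p in parts):
        raise ValueError("a partition is empty; use more documents or other fractions")
    return parts  # type: ignore[return-value]


def write_word_vectors(
    tokens: Sequence[str], path: str | Path, dim: int = 300, seed: int = 0
) -> Path:
    """Write a synthetic word-vector file in the standard ``word v1 ... vD``
    text format.  Vectors are random (seeded) and carry no class signal, so
    any trigger separability a model shows was learned, not leaked."""
    rng = np.random.default_rng(seed)
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for tok in tokens:
            vec = rng.uniform(-0.25, 0.25, size=dim)
            fh.write(tok + " " + " ".join(f"{v:.5f}" for v in vec) + "\n")
    return path
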