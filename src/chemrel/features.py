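"""Word/position feature encoding for relation instances.

Each token of a blinded sentence is represented by a 300-dimensional word
embedding concatenated with two 50-dimensional position embeddings, one per
candidate entity, for a 400-dimensional per-token feature vector.  Position
embeddings are indexed by the token's relative distance to the entity token,
shifted by an offset so the index is a non-negative integer; the position
tables are trained jointly with the model.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .corpus_io import LABELS
from .instances import CHEM_TOKEN, GENE_TOKEN, RelationInstance

WORD_DIM = 300
POS_DIM = 50
#: per-token feature width after embedding lookup: 300 + 2 x 50
FEATURE_DIM = WORD_DIM + 2 * POS_DIM

PAD_ID = 0
UNK_ID = 1

LABEL_TO_ID = {lab: i for i, lab in enumerate(LABELS)}
ID_TO_LABEL = dict(enumerate(LABELS))


@dataclass
class Vocabulary:
    """Token-to-index map; index 0 is padding, index 1 unknown-at-inference."""

    token_to_id: dict[str, int] = field(default_factory=dict)

    @classmethod
    def build(cls, token_lists: Iterable[Sequence[str]]) -> "Vocabulary":
        vocab = {"<pad>": PAD_ID, "<unk>": UNK_ID}
        for tokens in token_lists:
            for tok in tokens:
                if tok not in vocab:
                    vocab[tok] = len(vocab)
        for required in (CHEM_TOKEN, GENE_TOKEN):
            if required not in vocab:
                vocab[required] = len(vocab)
        return cls(vocab)

    def __len__(self) -> int:
        return len(self.token_to_id)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_id

    def id(self, token: str) -> int:
        return self.token_to_id.get(token, UNK_ID)

    def decode(self, ids: Sequence[int]) -> list[str]:
        rev = {i: t for t, i in self.token_to_id.items()}
        return [rev[i] for i in ids]


def load_pretrained(
    path: str | Path | None,
    vocab: Vocabulary,
    dim: int = WORD_DIM,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Build the V x D word-embedding matrix from a text word-vector file.

    File lines are ``token v1 ... vD``.  Tokens found in the file keep their
    pretrained vector; tokens missing from it (and all tokens when ``path``
    is None) get a seeded uniform(-0.25, 0.25) row.  Row 0 (padding) is
    zero.  Returns the matrix and the out-of-vocabulary rate over the
    non-special vocabulary.
    """
    rng = np.random.default_rng(seed)
    mat = rng.uniform(-0.25, 0.25, size=(len(vocab), dim)).astype(np.float64)
    mat[PAD_ID] = 0.0
    found = 0
    lookup = 0
    if path is not None:
        vectors: dict[str, np.ndarray] = {}
        with io.open(path, "r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                parts = line.rstrip("\n").split(" ")
                if len(parts) < 2:
                    continue
                if len(parts) - 1 != dim:
                    raise ValueError(
                        f"{path}: line {lineno}: expected {dim} components, "
                        f"got {len(parts) - 1}"
                    )
                if parts[0] in vocab:
                    vectors[parts[0]] = np.asarray(parts[1:], dtype=np.float64)
        for tok, idx in vocab.token_to_id.items():
            if idx in (PAD_ID, UNK_ID):
                continue
            lookup += 1
            if tok in vectors:
                mat[idx] = vectors[tok]
                found += 1
    else:
        lookup = len(vocab) - 2
    oov_rate = 1.0 - found / lookup if lookup else 0.0
    return mat, oov_rate


@dataclass(frozen=True)
class PositionIndexer:
    """Maps signed relative distances to non-negative embedding indices.

    The index of a distance d is clamp(d, -offset, offset-1) + offset, so
    indices live in [0, 2*offset - 1] and distance 0 maps to ``offset``.
    By default offset equals the sequence cap, giving the position table
    2*max_len rows.
    """

    offset: int = 150
    max_len: int = 150

    @property
    def table_size(self) -> int:
        return 2 * self.offset

    def index(self, distance: int) -> int:
        return int(np.clip(distance, -self.offset, self.offset - 1)) + self.offset


def position_index(distance: int, indexer: PositionIndexer) -> int:
    """Shifted (and clamped) non-negative index of a signed distance."""
    return indexer.index(distance)


def relative_distance(token_index: int, entity_token_pos: int) -> int:
    """Signed distance of a token to an entity token: 0 at the entity,
    negative to its left."""
    return token_index - entity_token_pos


@dataclass
class EncodedInstance:
    """Fixed-length index-sequence view of one relation instance."""

    word_ids: np.ndarray  # (max_len,) int
    pos_chem_ids: np.ndarray  # (max_len,) int
    pos_gene_ids: np.ndarray  # (max_len,) int
    label_id: int
    true_length: int
    tokens: list[str] = field(default_factory=list)  # window token strings
    instance: RelationInstance | None = None
    truncated: bool = False


def _truncation_window(n: int, cpos: int, gpos: int, max_len: int) -> tuple[int, int, bool]:
    """Window [lo, hi) of width <= max_len centered on the midpoint between
    the two entity tokens; flags the pathological case where the entities
    are too far apart to co-fit."""
    if n <= max_len:
        return 0, n, False
    lo_e, hi_e = min(cpos, gpos), max(cpos, gpos)
    if hi_e - lo_e + 1 > max_len:
        # both entities cannot fit: truncate from the right of the window
        # anchored at the chemical-side entity
        return lo_e, lo_e + max_len, True
    mid = (lo_e + hi_e) // 2
    lo = max(0, min(mid - max_len // 2, n - max_len))
    return lo, lo + max_len, False


def encode_instance(
    instance: RelationInstance,
    vocab: Vocabulary,
    indexer: PositionIndexer,
) -> EncodedInstance:
    """Encode blinded tokens as (word id, chem-position id, gene-position id)
    triples padded to ``indexer.max_len``.

    Sequences longer than the cap are cropped to a window containing both
    entity tokens; unknown tokens map to the UNK id (at training time the
    vocabulary is built from the training corpus so every token resolves).
    """
    toks = instance.blinded_tokens
    if not toks:
        raise ValueError("instance has no tokens")
    max_len = indexer.max_len
    lo, hi, flagged = _truncation_window(
        len(toks), instance.chem_token_pos, instance.gene_token_pos, max_len
    )
    if flagged:
        import logging

        logging.getLogger(__name__).warning(
            "%s: entities %d tokens apart exceed max_len %d; truncating",
            instance.pmid,
            abs(instance.chem_token_pos - instance.gene_token_pos),
            max_len,
        )
    window = toks[lo:hi]
    n = len(window)
    word_ids = np.full(max_len, PAD_ID, dtype=np.int64)
    pos_c = np.full(max_len, PAD_ID, dtype=np.int64)
    pos_g = np.full(max_len, PAD_ID, dtype=np.int64)
    cpos = instance.chem_token_pos - lo
    gpos = instance.gene_token_pos - lo
    for i, tok in enumerate(window):
        word_ids[i] = vocab.id(tok)
        pos_c[i] = indexer.index(relative_distance(i, cpos))
        pos_g[i] = indexer.index(relative_distance(i, gpos))
    return EncodedInstance(
        word_ids=word_ids,
        pos_chem_ids=pos_c,
        pos_gene_ids=pos_g,
        label_id=LABEL_TO_ID[instance.label],
        true_length=n,
        tokens=list(window),
        instance=instance,
        truncated=flagged or lo > 0 or hi < len(toks),
    )


def encode_corpus(
    instances: Sequence[RelationInstance],
    vocab: Vocabulary,
    indexer: PositionIndexer,
) -> list[EncodedInstance]:
    return [encode_instance(inst, vocab, indexer) for inst in instances]
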