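"""Post hoc analysis of word-level attention weights.

For every positive instance the token with the largest attention weight is
collected; tallying these per relation class surfaces the trigger words the
model learned (e.g. "inhibitor" for the downregulator class, "agonist" for
the agonist class) without any feature engineering.  The entity placeholder
tokens "chemical"/"gene" are excluded from the argmax by default: the
interesting signal is the context word carrying the relation, not the
blinded entity slot.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .instances import CHEM_TOKEN, GENE_TOKEN

PLACEHOLDERS = frozenset({CHEM_TOKEN, GENE_TOKEN})


@dataclass
class AttentionRecord:
    """Per-instance attention weights aligned to the blinded tokens."""

    tokens: list[str]
    alphas: np.ndarray
    label: str
    pmid: str = ""

    def __post_init__(self) -> None:
        self.alphas = np.asarray(self.alphas, dtype=float)
        if len(self.tokens) != len(self.alphas):
            raise ValueError(
                f"{len(self.tokens)} tokens vs {len(self.alphas)} weights"
            )
        if abs(float(self.alphas.sum()) - 1.0) > 1e-6:
            raise ValueError(f"attention weights sum to {self.alphas.sum():.8f}, not 1")


def max_attention_token(
    record: AttentionRecord, exclude_placeholders: bool = True
) -> tuple[str, bool]:
    """The token with the largest attention weight.

    Ties break toward the earliest token.  With ``exclude_placeholders``
    (default) the blinded entity tokens are skipped; if every token is a
    placeholder the best placeholder is returned with a flag.  Returns
    (token, is_placeholder_fallback).
    """
    order = np.argsort(-record.alphas, kind="stable")
    if exclude_placeholders:
        for i in order:
            if record.tokens[i] not in PLACEHOLDERS:
                return record.tokens[i], False
        return record.tokens[order[0]], True
    return record.tokens[order[0]], False


@dataclass
class KeywordSummary:
    """Top max-attention words per relation class with counts and the
    percentage of that class's positive instances they account for."""

    per_class: dict[str, list[tuple[str, int, float]]] = field(default_factory=dict)
    class_sizes: dict[str, int] = field(default_factory=dict)


def keyword_table(
    records: Sequence[AttentionRecord],
    k: int = 5,
    exclude_placeholders: bool = True,
) -> KeywordSummary:
    """Tally max-attention words over positive instances, per class.

    Percentages are count / (positive instances of the class) * 100, so the
    per-class percentages sum to at most 100.
    """
    tallies: dict[str, Counter] = {}
    sizes: dict[str, int] = {}
    for rec in records:
        if rec.label == "NA":
            continue
        word, _ = max_attention_token(rec, exclude_placeholders)
        tallies.setdefault(rec.label, Counter())[word] += 1
        sizes[rec.label] = sizes.get(rec.label, 0) + 1
    summary = KeywordSummary(class_sizes=sizes)
    for label, counter in sorted(tallies.items()):
        n = sizes[label]
        top = counter.most_common(k)
        summary.per_class[label] = [
            (word, count, 100.0 * count / n) for word, count in top
        ]
    return summary


def format_keyword_table(summary: KeywordSummary) -> str:
    """Render in the conventional 'word (count, percent%)' style."""
    lines = []
    for label, rows in summary.per_class.items():
        cells = ", ".join(f"{w} ({c}, {pct:.1f}%)" for w, c, pct in rows)
        lines.append(f"{label}: {cells}")
    return "\n".join(lines)


def render_heat(record: AttentionRecord) -> list[dict]:
    """Per-token display intensities, normalized to [0, 1] by the maximum
    weight.  Structured data suitable for text or HTML rendering; the raw
    weights stay recoverable."""
    peak = float(record.alphas.max())
    return [
        {
            "token": tok,
            "weight": float(a),
            "intensity": float(a) / peak if peak > 0 else 0.0,
        }
        for tok, a in zip(record.tokens, record.alphas)
    ]
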