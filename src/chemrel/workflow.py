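"""End-to-end experiment orchestration.

``run_experiment`` drives the whole pipeline — corpus (on disk or
synthetic) -> relation instances -> encoded features -> model training ->
prediction file -> tuple evaluation -> attention keyword report — from one
serializable configuration, so a run is reproducible from its config and
seed alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import corpus_io, evaluation, features, instances as ig, models, synthetic
from .attention_analysis import AttentionRecord, KeywordSummary, keyword_table
from .corpus_io import CorpusStats, PredictionRecord
from .features import PositionIndexer, Vocabulary
from .models import ModelConfig, TrainedModel

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed to reproduce one experiment."""

    model: ModelConfig = field(default_factory=ModelConfig)
    synth: synthetic.SynthConfig | None = field(default_factory=synthetic.SynthConfig)
    corpus_dir: str | None = None  # read TSVs from here instead of generating
    pretrained_vectors: str | None = None
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    out_dir: str = "runs/latest"
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class ExperimentResult:
    trained: TrainedModel
    vocab: Vocabulary
    stats: CorpusStats
    report: evaluation.EvalReport
    tuple_report: evaluation.EvalReport
    confusion: evaluation.ConfusionMatrix
    keywords: KeywordSummary | None
    predictions_path: Path | None
    attention_records: list[AttentionRecord]
    unreachable_gold: int
    #: fraction of positive test instances whose max-attention word equals
    #: the planted trigger (None without truth table or attention model)
    trigger_recovery: float | None = None


def _stage(name: str):
    logger.info("stage: %s", name)
    return time.time()


def build_dataset(corpus: synthetic.SynthCorpus):
    """Corpus -> labeled relation instances, document by document."""
    gold_idx = ig.index_gold(corpus.relations)
    all_instances = []
    for doc in corpus.documents:
        all_instances.extend(ig.build_instances(doc, corpus.mentions, gold_idx))
    return all_instances


def _predictions(insts, pred_ids) -> list[PredictionRecord]:
    recs = []
    for inst, pid in zip(insts, pred_ids):
        label = features.ID_TO_LABEL[int(pid)]
        if label == "NA":
            continue
        recs.append(
            PredictionRecord(inst.pmid, label, inst.chem.term_id, inst.gene.term_id)
        )
    return recs


def run_experiment(config: RunConfig) -> ExperimentResult:
    """Execute the full pipeline and write all artifacts to
    ``config.out_dir``.  Any stage failure aborts with a stage-named error."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "corpus"
    try:
        t0 = _stage(stage)
        if config.corpus_dir is not None:
            cdir = Path(config.corpus_dir)
            corpus = synthetic.SynthCorpus(
                documents=corpus_io.read_abstracts(cdir / "abstracts.tsv"),
                mentions=corpus_io.read_entities(cdir / "entities.tsv"),
                relations=corpus_io.read_gold_relations(cdir / "relations.tsv"),
                truth=[],
                config=config.synth or synthetic.SynthConfig(),
            )
        else:
            corpus = synthetic.generate(config.synth or synthetic.SynthConfig())
        train_c, dev_c, test_c = synthetic.split(
            corpus, config.split_fractions, seed=config.seed
        )

        stage = "instances"
        _stage(stage)
        train_inst = build_dataset(train_c)
        dev_inst = build_dataset(dev_c)
        test_inst = build_dataset(test_c)
        stats = corpus_io.corpus_stats(
            corpus.documents, corpus.mentions, train_inst + dev_inst + test_inst
        )
        unreachable = ig.unreachable_gold(
            train_inst + dev_inst + test_inst, corpus.relations
        )
        logger.info(
            "corpus: %d docs, %.1f entities/doc, %d positive relations, "
            "%d instances (%d unreachable gold)",
            stats.n_docs, stats.avg_entities_per_doc, stats.n_positive_relations,
            stats.n_instances, len(unreachable),
        )

        stage = "features"
        _stage(stage)
        vocab = Vocabulary.build(i.blinded_tokens for i in train_inst)
        indexer = PositionIndexer(
            offset=config.model.pos_offset, max_len=config.model.max_len
        )
        word_init, oov = features.load_pretrained(
            config.pretrained_vectors, vocab, seed=config.seed
        )
        if config.pretrained_vectors:
            logger.info("pretrained vectors: OOV rate %.3f", oov)
        enc_train = features.encode_corpus(train_inst, vocab, indexer)
        enc_dev = features.encode_corpus(dev_inst, vocab, indexer)
        enc_test = features.encode_corpus(test_inst, vocab, indexer)

        stage = "train"
        _stage(stage)
        cfg = dataclasses.replace(config.model, seed=config.seed)
        trained = models.train_model(enc_train, enc_dev, cfg, word_init=word_init)

        stage = "predict"
        _stage(stage)
        pred_ids, alphas = models.predict(trained.model, enc_test)
        pred_records = _predictions(test_inst, pred_ids)
        pred_path = out / "predictions.tsv"
        corpus_io.write_predictions(pred_records, pred_path)

        stage = "evaluate"
        _stage(stage)
        gold_ids = [e.label_id for e in enc_test]
        report = evaluation.micro_prf(gold_ids, pred_ids)
        cm = evaluation.confusion(gold_ids, pred_ids)
        tuple_report = evaluation.tuple_eval(test_c.relations, pred_records)

        stage = "attention"
        _stage(stage)
        keywords = None
        trigger_recovery = None
        att_records: list[AttentionRecord] = []
        if alphas is not None:
            for enc, a in zip(enc_test, alphas):
                att_records.append(
                    AttentionRecord(
                        tokens=enc.tokens,
                        alphas=a / a.sum(),
                        label=features.ID_TO_LABEL[enc.label_id],
                        pmid=enc.instance.pmid if enc.instance else "",
                    )
                )
            keywords = keyword_table(att_records)
            if test_c.truth:
                from .attention_analysis import max_attention_token

                truth = {
                    (t.pmid, t.chem_tid, t.gene_tid): t.trigger for t in test_c.truth
                }
                hits = total = 0
                for inst, rec in zip(test_inst, att_records):
                    trig = truth.get((inst.pmid, inst.chem.term_id, inst.gene.term_id))
                    if trig is None:
                        continue
                    total += 1
                    hits += max_attention_token(rec)[0] == trig
                trigger_recovery = hits / total if total else None

        stage = "artifacts"
        _stage(stage)
        summary = {
            "config": config.to_dict(),
            "corpus_stats": dataclasses.asdict(stats),
            "unreachable_gold": len(unreachable),
            "training_history": trained.history,
            "best_epoch": trained.best_epoch,
            "best_dev_micro_f1": trained.best_dev_f1,
            "test_micro": report.as_dict(),
            "test_tuple_eval": tuple_report.as_dict(),
            "confusion_matrix": cm.counts.tolist(),
            "keywords": keywords.per_class if keywords else None,
            "trigger_recovery": trigger_recovery,
            "elapsed_s": time.time() - t0,
        }
        (out / "report.json").write_text(json.dumps(summary, indent=2, default=str))
        (out / "per_class.txt").write_text(
            evaluation.format_per_class(report.per_class)
        )
        return ExperimentResult(
            trained=trained,
            vocab=vocab,
            stats=stats,
            report=report,
            tuple_report=tuple_report,
            confusion=cm,
            keywords=keywords,
            predictions_path=pred_path,
            attention_records=att_records,
            unreachable_gold=len(unreachable),
            trigger_recovery=trigger_recovery,
        )
    except Exception as exc:
        raise RuntimeError(f"experiment failed in stage '{stage}': {exc}") from exc


def grid_search(
    config: RunConfig, grid: dict[str, Sequence]
) -> tuple[RunConfig, list[dict]]:
    """Exhaustive search over ModelConfig fields, best by dev micro-F1.

    ``grid`` maps ModelConfig field names to candidate value lists.  Ties
    break toward the earlier point in grid order.  Returns the winning
    config and the full results table.
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("empty grid")
    keys = list(grid)
    combos: list[dict] = [{}]
    for k in keys:
        combos = [dict(c, **{k: v}) for c in combos for v in grid[k]]
    results = []
    best: tuple[float, int] | None = None
    best_cfg = None
    for i, combo in enumerate(combos):
        cfg = dataclasses.replace(
            config, model=dataclasses.replace(config.model, **combo)
        )
        cfg.out_dir = str(Path(config.out_dir) / f"grid_{i}")
        res = run_experiment(cfg)
        row = {**combo, "dev_micro_f1": res.trained.best_dev_f1}
        results.append(row)
        logger.info("grid point %d/%d: %s", i + 1, len(combos), row)
        if best is None or res.trained.best_dev_f1 > best[0]:
            best = (res.trained.best_dev_f1, i)
            best_cfg = cfg
    assert best_cfg is not None
    return best_cfg, results
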