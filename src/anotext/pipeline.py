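"""End-to-end analysis pipeline: one report per document.

Ties the four stages together: preparation, sentiment (dictionary and/or
network), emotion profiling, difficulty-area scoring.  Stages are
independently switchable — a stage runs exactly when its resources are
supplied — and every report carries a provenance block so a run can be
reproduced.  Outputs are plain dicts ready for JSON-lines serialization.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .difficulties import profile_areas
from .emotions import EmotionTaxonomy, profile_document
from .lexicons import AffectiveWordList, DifficultyLexicons, PolarityLexicon
from .sentiment import score_document
from .textprep import BasicFormMap, RawDocument, StopList, prepare_term_bag

logger = logging.getLogger(__name__)

__all__ = ["PipelineResources", "AnalysisReport", "run_pipeline"]


@dataclass(frozen=True)
class PipelineResources:
    """Resources enabling each stage; None disables the stage."""

    stoplist: StopList | None = None
    basic_forms: BasicFormMap | None = None
    polarity: PolarityLexicon | None = None
    affective: AffectiveWordList | None = None
    taxonomy: EmotionTaxonomy | None = None
    difficulty: DifficultyLexicons | None = None
    rnn_model: object | None = None            # SentimentGRU
    embeddings: object | None = None           # EmbeddingTable
    provenance: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class AnalysisReport:
    """Per-document results of all enabled stages; absent stages are None."""

    doc_id: str
    dict_sentiment: dict | None
    rnn_sentiment: dict | None
    emotions: dict | None
    difficulties: dict | None
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "doc_id": self.doc_id,
            "dict_sentiment": self.dict_sentiment,
            "rnn_sentiment": self.rnn_sentiment,
            "emotions": self.emotions,
            "difficulties": self.difficulties,
            "provenance": self.provenance,
        }


def _config_hash(resources: PipelineResources) -> str:
    payload = {
        "stoplist": sorted(resources.stoplist.terms) if resources.stoplist else None,
        "basic_forms": sorted(resources.basic_forms.entries.items())
        if resources.basic_forms
        else None,
        "polarity": sorted(resources.polarity.entries.items())
        if resources.polarity
        else None,
        "affective_n": len(resources.affective) if resources.affective else None,
        "difficulty": {a: sorted(s) for a, s in resources.difficulty.areas.items()}
        if resources.difficulty
        else None,
        "extra": dict(resources.provenance),
    }
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()
    return digest[:16]


def run_pipeline(
    corpus: Sequence[RawDocument],
    resources: PipelineResources,
    with_rnn: bool | None = None,
) -> list[AnalysisReport]:
    """Run every enabled stage over a corpus.

    ``with_rnn`` defaults to "enabled iff a model and embeddings were
    supplied"; requesting the network stage without them is an error
    raised before any document is processed.  Deterministic given
    resources and model; an empty corpus yields an empty report list.
    """
    from . import __version__

    if with_rnn is None:
        with_rnn = resources.rnn_model is not None
    if with_rnn and (resources.rnn_model is None or resources.embeddings is None):
        raise ValueError("network stage enabled but model/embeddings missing")

    provenance = {
        "package_version": __version__,
        "config_hash": _config_hash(resources),
        **dict(resources.provenance),
    }

    reports: list[AnalysisReport] = []
    for doc in corpus:
        t0 = time.perf_counter()
        bag = prepare_term_bag(doc, resources.stoplist, resources.basic_forms)
        dict_res = (
            score_document(bag, resources.polarity).to_dict()
            if resources.polarity is not None
            else None
        )
        rnn_res = None
        if with_rnn:
            from .gru import predict_document

            rnn_res = predict_document(
                resources.rnn_model, resources.embeddings, doc
            ).to_dict()
        emo_res = (
            profile_document(
                bag, resources.affective, resources.taxonomy or EmotionTaxonomy()
            ).to_dict()
            if resources.affective is not None
            else None
        )
        diff_res = (
            profile_areas(bag, resources.difficulty).to_dict()
            if resources.difficulty is not None
            else None
        )
        reports.append(
            AnalysisReport(doc.doc_id, dict_res, rnn_res, emo_res, diff_res,
                           provenance)
        )
        logger.info("analyzed %s in %.1f ms", doc.doc_id,
                    1e3 * (time.perf_counter() - t0))
    return reports
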