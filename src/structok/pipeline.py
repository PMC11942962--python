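"""End-to-end orchestration: tokenize, train, evaluate, ablate.

Thin functional layer over :class:`~structok.tokenizer.StructureTokenizer`
and :class:`~structok.model.SequenceStructureClassifier`; also used by the
command-line interface. Every run derives its randomness from one seed and
can emit a JSON manifest for provenance.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np

from .core import LabelTable, ProteinStructure, TokenizedProtein
from .metrics import MetricsResult, PredictionTable, fmax
from .model import SequenceStructureClassifier
from .tokenizer import StructureTokenizer

__all__ = [
    "train_classifier",
    "evaluate_split",
    "run_ablation_suite",
    "ABLATION_SUITE_MODES",
    "write_manifest",
]

ABLATION_SUITE_MODES = (
    "full",
    "single_kernel:3",
    "single_kernel:5",
    "single_kernel:7",
    "embedding_only",
)


def train_classifier(
    tokens: list[TokenizedProtein],
    labels: LabelTable,
    n_structure_vocab: int,
    seed: int = 0,
    **clf_params,
) -> SequenceStructureClassifier:
    """Fit a classifier on the table's train split (selection on valid)."""
    clf = SequenceStructureClassifier(
        n_structure_vocab=n_structure_vocab, seed=seed, **clf_params
    )
    return clf.fit(tokens, labels)


def evaluate_split(
    clf: SequenceStructureClassifier,
    tokens: list[TokenizedProtein],
    labels: LabelTable,
    split: str = "test",
) -> MetricsResult:
    """Fmax/AUPR of a fitted classifier on one split of the label table."""
    sub = labels.subset(split)
    by_id = {t.id: t for t in tokens}
    split_tokens = [by_id[p] for p in sub.protein_ids]
    scores = clf.predict_proba(split_tokens)
    table = PredictionTable(
        protein_ids=sub.protein_ids,
        term_ids=sub.term_ids,
        scores=scores,
        truth=sub.truth,
    )
    return fmax(table)


def run_ablation_suite(
    tokens: list[TokenizedProtein],
    labels: LabelTable,
    n_structure_vocab: int,
    seed: int = 0,
    modes: tuple[str, ...] = ABLATION_SUITE_MODES,
    **clf_params,
) -> list[dict]:
    """Train every ablation mode under identical seed and budget.

    Returns one row per mode: ``{"mode", "fmax", "aupr", "seed"}``, test-split
    metrics from the validation-selected checkpoint.
    """
    rows = []
    for mode in modes:
        clf = SequenceStructureClassifier(
            n_structure_vocab=n_structure_vocab,
            ablation_mode=mode,
            seed=seed,
            **clf_params,
        )
        clf.fit(tokens, labels)
        result = evaluate_split(clf, tokens, labels, "test")
        rows.append(
            {"mode": mode, "fmax": result.fmax, "aupr": result.aupr, "seed": seed}
        )
    return rows


def tokenize_corpus(
    structures: list[ProteinStructure],
    n_tokens: int,
    seed: int = 0,
    **tok_params,
) -> tuple[StructureTokenizer, list[TokenizedProtein]]:
    """Fit a structure tokenizer on a corpus and tokenize it."""
    tok = StructureTokenizer(n_tokens=n_tokens, seed=seed, **tok_params)
    tok.fit(structures)
    return tok, tok.transform(structures)


def write_manifest(path: str | Path, config: dict, seed: int) -> None:
    """Write a JSON run manifest (config hash, seed, versions)."""
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": config,
        "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
        "seed": seed,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
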