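"""End-to-end orchestration: featurize, train, predict, sweep, evaluate.

The functions here are thin compositions of the other modules and define
the package's file-level contract: query FASTA + resolved-index TSV in,
MCSbase + SS + hits alongside, prediction TSV and evaluation JSON out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import crf, decision, metrics
from .annotation import ChainAnnotation, add_near_disorder, two_state_labels, DEFAULT_K
from .features import DEFAULT_SS_ALPHABET, FeatureMatrix, SSAlphabet, assemble, encode_ss
from .mcsbase import MCSDatabase, exclude_matches
from .mcs_profile import AlignmentHit, HitSelectionParams, mcs_for_query

logger = logging.getLogger("disomcs")

EXIT_MISSING_INPUT = 2
EXIT_DIMENSION = 3


class PipelineError(RuntimeError):
    """Pipeline failure carrying the CLI exit code."""

    def __init__(self, message: str, exit_code: int = EXIT_MISSING_INPUT):
        super().__init__(message)
        self.exit_code = exit_code


@dataclass
class PipelineConfig:
    """Shared knobs of the train/predict/evaluate passes."""

    k: int = DEFAULT_K
    hit_params: HitSelectionParams = field(default_factory=HitSelectionParams)
    decision_config: decision.DecisionConfig = field(default_factory=decision.DecisionConfig)
    train_config: crf.TrainConfig = field(default_factory=crf.TrainConfig)
    ss_alphabet: SSAlphabet = DEFAULT_SS_ALPHABET
    exclude_exact_matches: bool = True
    seed: int = 0


def _hits_by_query(hits: Iterable[AlignmentHit]) -> dict[str, list[AlignmentHit]]:
    out: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        out.setdefault(h.query_id, []).append(h)
    return out


def featurize(
    sequences: dict[str, str],
    db: MCSDatabase,
    ss: dict[str, str],
    hits: Iterable[AlignmentHit],
    config: PipelineConfig | None = None,
) -> dict[str, FeatureMatrix]:
    """Build the 12-column feature matrix for every query chain.

    A chain absent from the hit collection gets an all-zero MCS block
    (no homology signal) but is still featurized and predicted.
    """
    config = config or PipelineConfig()
    grouped = _hits_by_query(hits)
    out: dict[str, FeatureMatrix] = {}
    for cid, seq in sequences.items():
        if cid not in ss:
            raise PipelineError(
                f"no secondary-structure record for chain {cid!r}", EXIT_DIMENSION
            )
        if len(ss[cid]) != len(seq):
            raise PipelineError(
                f"chain {cid!r}: SS length {len(ss[cid])} != sequence length {len(seq)}",
                EXIT_DIMENSION,
            )
        profile = mcs_for_query(seq, db, grouped.get(cid, []), config.hit_params)
        out[cid] = assemble(profile, encode_ss(ss[cid], config.ss_alphabet))
    return out


def run_train(
    chains: Sequence[ChainAnnotation],
    db: MCSDatabase,
    ss: dict[str, str],
    hits: Iterable[AlignmentHit],
    config: PipelineConfig | None = None,
    model_path=None,
) -> tuple[crf.CRFModel, dict]:
    """Three-state the training chains, featurize, and fit the CRF.

    With ``exclude_exact_matches`` set, database records whose sequence
    exactly equals a training query are dropped first, so the model never
    sees its own answers.  The log records the objective trajectory and the
    final Viterbi token accuracy on the training labels.
    """
    config = config or PipelineConfig()
    if not chains:
        raise PipelineError("empty training set", EXIT_MISSING_INPUT)
    sequences = {c.chain_id: c.sequence for c in chains}
    if config.exclude_exact_matches:
        before = len(db)
        db = exclude_matches(db, sequences.values())
        logger.info("fairness exclusion removed %d database records", before - len(db))
    fms = featurize(sequences, db, ss, hits, config)
    dataset = []
    labels3: dict[str, str] = {}
    for c in chains:
        labels3[c.chain_id] = add_near_disorder(two_state_labels(c), config.k)
        dataset.append((fms[c.chain_id], labels3[c.chain_id]))
    model, log = crf.train(dataset, config.train_config)
    correct = total = 0
    for c in chains:
        path = crf.predict_path(model, fms[c.chain_id])
        correct += sum(a == b for a, b in zip(path, labels3[c.chain_id]))
        total += len(path)
    log["token_accuracy"] = correct / total
    logger.info(
        "trained on %d chains (%d residues); token accuracy %.4f",
        len(chains), total, log["token_accuracy"],
    )
    if model_path is not None:
        crf.save_model(model, model_path)
    return model, log


def predict_marginals(
    model: crf.CRFModel,
    sequences: dict[str, str],
    db: MCSDatabase,
    ss: dict[str, str],
    hits: Iterable[AlignmentHit],
    config: PipelineConfig | None = None,
) -> dict[str, crf.Marginals]:
    """Posterior (O, N, D) marginals for each query chain."""
    config = config or PipelineConfig()
    fms = featurize(sequences, db, ss, hits, config)
    return {cid: crf.predict_marginals(model, fm) for cid, fm in fms.items()}


def run_predict(
    model: crf.CRFModel,
    sequences: dict[str, str],
    db: MCSDatabase,
    ss: dict[str, str],
    hits: Iterable[AlignmentHit],
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Per-residue prediction table.

    Columns: chain_id, position (1-based), residue, P_order, P_near,
    P_disorder, three_state_call (argmax), binary_call (O/D after the
    configured scheme).
    """
    config = config or PipelineConfig()
    margs = predict_marginals(model, sequences, db, ss, hits, config)
    rows = []
    for cid, seq in sequences.items():
        marg = margs[cid]
        three = decision.base_call(marg)
        binary = decision.apply_scheme(marg, config.decision_config)
        for p in range(len(seq)):
            rows.append(
                {
                    "chain_id": cid,
                    "position": p + 1,
                    "residue": seq[p],
                    "P_order": round(float(marg.values[p, 0]), 6),
                    "P_near": round(float(marg.values[p, 1]), 6),
                    "P_disorder": round(float(marg.values[p, 2]), 6),
                    "three_state_call": three[p],
                    "binary_call": "D" if binary[p] else "O",
                }
            )
    return pd.DataFrame(rows)


def run_evaluate(
    predictions: pd.DataFrame,
    truth: dict[str, str],
    bootstrap: tuple[int, float] | None = None,
    seed: int = 0,
) -> dict:
    """Score a prediction table against two-state truth labels.

    ``bootstrap`` is (reps, frac) for per-chain bootstrap standard errors of
    Sn, Sp and Sw.  AUC ranks residues by P_disorder.
    """
    chain_ids = [c for c in predictions["chain_id"].unique() if c in truth]
    if not chain_ids:
        raise PipelineError("no overlapping chain ids between predictions and truth")
    chains = []
    scores = []
    for cid in chain_ids:
        sub = predictions[predictions["chain_id"] == cid].sort_values("position")
        if len(sub) != len(truth[cid]):
            raise PipelineError(
                f"chain {cid!r}: {len(sub)} predicted residues vs "
                f"{len(truth[cid])} truth labels", EXIT_DIMENSION,
            )
        chains.append(("".join(sub["binary_call"]), truth[cid]))
        scores.append(sub["P_disorder"].to_numpy())
    report = metrics.evaluate(chains, scores)
    report["n_chains"] = len(chain_ids)
    if bootstrap is not None:
        reps, frac = bootstrap

        def _sn(p, t):
            c = metrics.confusion(p, t)
            return 100.0 * c.tp / c.nd if c.nd else np.nan

        def _sp(p, t):
            c = metrics.confusion(p, t)
            return 100.0 * c.tn / c.no if c.no else np.nan

        def _sw(p, t):
            c = metrics.confusion(p, t)
            return metrics.sw(c) if c.nd and c.no else np.nan

        for name, fn in (("Sn", _sn), ("Sp", _sp), ("Sw", _sw)):
            report[f"SE_{name}"] = round(
                metrics.bootstrap_se(chains, fn, frac=frac, reps=reps, seed=seed), 4
            )
    return report


def run_sweep(
    model: crf.CRFModel,
    sequences: dict[str, str],
    db: MCSDatabase,
    ss: dict[str, str],
    hits: Iterable[AlignmentHit],
    truth: dict[str, str],
    scheme: str = decision.SCHEME_II,
    grid: Sequence[float] = decision.DEFAULT_GRID,
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, float]:
    """Threshold sweep of the configured scheme over the given chains."""
    margs = predict_marginals(model, sequences, db, ss, hits, config)
    pairs = [(margs[cid], truth[cid]) for cid in sequences if cid in truth]
    if not pairs:
        raise PipelineError("no overlapping chain ids between queries and truth")
    return decision.sweep_threshold(pairs, scheme=scheme, grid=grid)
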