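"""Binary disorder evaluation: Sn, Sp, ACC, MCC, the weighted score Sw, AUC,
and per-chain bootstrap standard errors.

Disorder is the positive class throughout.  Ground truth is always the
two-state order/disorder annotation; the near-disorder training class never
reaches evaluation.  Sw weights true calls by the *opposite* class
prevalence (W_d = ordered fraction applied to disorder calls, W_o =
disordered fraction applied to order calls), which makes it algebraically
identical to Sn + Sp - 100 in percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .annotation import DISORDER, ORDER


class MetricError(ValueError):
    """Raised for undefined metrics or inconsistent inputs."""


def _as_mask(x, what: str) -> np.ndarray:
    """Coerce a {O,D} string or boolean sequence to a disorder mask."""
    if isinstance(x, str):
        bad = set(x) - {ORDER, DISORDER}
        if bad:
            raise MetricError(f"{what}: unexpected symbols {sorted(bad)}")
        return np.fromiter((c == DISORDER for c in x), dtype=bool, count=len(x))
    return np.asarray(x, dtype=bool)


@dataclass(frozen=True)
class ConfusionCounts:
    """A 2x2 table with disorder positive, plus the class-prevalence weights."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise MetricError("confusion counts must be non-negative")

    @property
    def nd(self) -> int:
        """Total disordered residues (positives)."""
        return self.tp + self.fn

    @property
    def no(self) -> int:
        """Total ordered residues (negatives)."""
        return self.tn + self.fp

    @property
    def wo(self) -> float:
        """Fraction of disordered residues (weight applied to order calls)."""
        return self.nd / (self.nd + self.no)

    @property
    def wd(self) -> float:
        """Fraction of ordered residues (weight applied to disorder calls)."""
        return self.no / (self.nd + self.no)

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


def confusion(pred, truth) -> ConfusionCounts:
    """Count TP/FP/TN/FN between a predicted mask and two-state truth.

    Both arguments accept an {O,D} string or a boolean disorder mask.
    """
    p = _as_mask(pred, "prediction")
    t = _as_mask(truth, "truth")
    if len(p) != len(t):
        raise MetricError(f"prediction length {len(p)} != truth length {len(t)}")
    return ConfusionCounts(
        tp=int((p & t).sum()),
        fp=int((p & ~t).sum()),
        tn=int((~p & ~t).sum()),
        fn=int((~p & t).sum()),
    )


def basic_rates(c: ConfusionCounts) -> tuple[float | None, float | None, float | None]:
    """(Sn, Sp, ACC) in percent; an undefined rate (empty class) is None."""
    sn = 100.0 * c.tp / c.nd if c.nd > 0 else None
    sp = 100.0 * c.tn / c.no if c.no > 0 else None
    acc = (sn + sp) / 2.0 if sn is not None and sp is not None else None
    return sn, sp, acc


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0.0 when any denominator factor is 0."""
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def mcc_is_defined(c: ConfusionCounts) -> bool:
    return (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn) != 0


def sw(c: ConfusionCounts) -> float:
    """Weighted score in percent, from the weighted-count form.

    Sw = (Wd*TP - Wo*FP + Wo*TN - Wd*FN) / (Wd*Nd + Wo*No); numerically this
    equals Sn + Sp - 100 whenever both classes are present.
    """
    if c.nd == 0 or c.no == 0:
        raise MetricError("Sw requires both ordered and disordered residues")
    num = c.wd * c.tp - c.wo * c.fp + c.wo * c.tn - c.wd * c.fn
    den = c.wd * c.nd + c.wo * c.no
    return 100.0 * num / den


def sw_from_rates(sn: float, sp: float) -> float:
    """Sw in percent from printed Sn/Sp percentages (the linear identity)."""
    return sn + sp - 100.0


def acc_from_rates(sn: float, sp: float) -> float:
    """Balanced accuracy in percent from printed Sn/Sp percentages."""
    return (sn + sp) / 2.0


def roc_auc(scores: Sequence[float], truth) -> float:
    """Tie-corrected AUC of per-residue disorder scores against two-state truth.

    Equals P(score_D > score_O) + 0.5 * P(equal) over disorder/order pairs.
    """
    t = _as_mask(truth, "truth")
    s = np.asarray(scores, dtype=np.float64)
    if len(s) != len(t):
        raise MetricError(f"scores length {len(s)} != truth length {len(t)}")
    if t.all() or (~t).all():
        raise MetricError("AUC undefined: only one class present")
    return float(roc_auc_score(t, s))


def bootstrap_se(
    chains: Sequence[tuple],
    measure: Callable[[np.ndarray, np.ndarray], float],
    frac: float = 0.8,
    reps: int = 1000,
    seed: int = 0,
) -> float:
    """Bootstrap standard error of a pooled-residue measure over chains.

    Each replicate draws ``floor(frac * n)`` chains without replacement,
    pools their residues, and evaluates ``measure(pred_pool, truth_pool)``;
    the SE is the sample standard deviation (n-1 denominator) across
    replicates.  Chains (the prediction "targets") are the resampling unit.
    """
    if len(chains) < 2:
        raise MetricError("bootstrap needs at least 2 chains")
    if reps < 2:
        raise MetricError("bootstrap needs at least 2 replicates")
    rng = np.random.default_rng(seed)
    n_take = max(1, int(frac * len(chains)))
    preds = [_as_mask(p, "prediction") if isinstance(p, str) else np.asarray(p) for p, _ in chains]
    truths = [_as_mask(t, "truth") for _, t in chains]
    vals = np.empty(reps)
    for r in range(reps):
        pick = rng.choice(len(chains), size=n_take, replace=False)
        p = np.concatenate([preds[i] for i in pick])
        t = np.concatenate([truths[i] for i in pick])
        vals[r] = measure(p, t)
    return float(np.std(vals, ddof=1))


def evaluate(
    chains: Sequence[tuple],
    scores: Sequence[Sequence[float]] | None = None,
) -> dict:
    """Pooled evaluation report over (pred, truth) chains, percentages rounded
    as in standard report tables (2 decimals).

    ``scores`` optionally supplies per-chain P(disorder) score arrays for AUC.
    """
    total = ConfusionCounts(0, 0, 0, 0)
    for pred, truth in chains:
        total = total + confusion(pred, truth)
    sn, sp, acc = basic_rates(total)
    report = {
        "TP": total.tp,
        "FP": total.fp,
        "TN": total.tn,
        "FN": total.fn,
        "Sn": None if sn is None else round(sn, 2),
        "Sp": None if sp is None else round(sp, 2),
        "ACC": None if acc is None else round(acc, 2),
        "MCC": round(mcc(total), 4),
        "MCC_defined": mcc_is_defined(total),
        "Sw": round(sw(total), 2) if total.nd > 0 and total.no > 0 else None,
    }
    if scores is not None:
        pooled_scores = np.concatenate([np.asarray(s, dtype=np.float64) for s in scores])
        pooled_truth = np.concatenate([_as_mask(t, "truth") for _, t in chains])
        report["AUC"] = round(roc_auc(pooled_scores, pooled_truth), 4)
    return report
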