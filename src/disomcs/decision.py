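"""Reduce three-class posteriors to binary order/disorder calls.

The base determination takes the argmax of the (O, N, D) marginals.  Two
alternative threshold schemes then resolve residues into the final binary
call:

* scheme I  — a residue not already called disorder becomes disorder when
  its near-disorder probability exceeds tau (default 0.4);
* scheme II — a residue is disorder exactly when its disorder probability
  exceeds tau (default 0.03).

Sweeping tau against pooled Sn/Sp/Sw locates the Sw-maximizing operating
point; under scheme II the sweep traces the ROC of the P(D) score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import STATES
from .crf import Marginals
from . import metrics

SCHEME_I = "I"
SCHEME_II = "II"

DEFAULT_TAU = {SCHEME_I: 0.4, SCHEME_II: 0.03}


@dataclass(frozen=True)
class DecisionConfig:
    """Which scheme to apply and at what threshold."""

    scheme: str = SCHEME_II
    tau: float | None = None

    def __post_init__(self) -> None:
        if self.scheme not in (SCHEME_I, SCHEME_II):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.tau is not None and not 0.0 <= self.tau <= 1.0:
            raise ValueError("tau must lie in [0, 1]")

    @property
    def effective_tau(self) -> float:
        return DEFAULT_TAU[self.scheme] if self.tau is None else self.tau


def base_call(marginals: Marginals) -> str:
    """Per-position argmax over (O, N, D); ties break D > N > O."""
    v = marginals.values
    # reversed argmax prefers the later label (D) on exact ties
    idx = 2 - np.argmax(v[:, ::-1], axis=1)
    return "".join(STATES[i] for i in idx)


def apply_scheme_I(marginals: Marginals, tau: float = 0.4) -> np.ndarray:
    """Binary disorder mask: base-call D, or P(N) > tau on a non-D residue."""
    base = base_call(marginals)
    is_d = np.fromiter((c == "D" for c in base), dtype=bool, count=len(base))
    return is_d | (~is_d & (marginals.values[:, 1] > tau))


def apply_scheme_II(marginals: Marginals, tau: float = 0.03) -> np.ndarray:
    """Binary disorder mask: P(D) > tau."""
    return marginals.values[:, 2] > tau


def apply_scheme(marginals: Marginals, config: DecisionConfig) -> np.ndarray:
    if config.scheme == SCHEME_I:
        return apply_scheme_I(marginals, config.effective_tau)
    return apply_scheme_II(marginals, config.effective_tau)


DEFAULT_GRID = tuple(np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2))


def sweep_threshold(
    chains: Sequence[tuple[Marginals, str]],
    scheme: str = SCHEME_II,
    grid: Sequence[float] = DEFAULT_GRID,
) -> tuple[pd.DataFrame, float]:
    """Evaluate pooled Sn/Sp/Sw over a threshold grid.

    ``chains`` pairs each chain's marginals with its two-state truth.
    Returns the sweep table (tau, TP, FP, TN, FN, Sn, Sp, Sw) and the
    Sw-maximizing tau (smallest on ties).
    """
    if len(grid) == 0:
        raise ValueError("threshold grid must be non-empty")
    rows = []
    for tau in grid:
        cfg = DecisionConfig(scheme=scheme, tau=float(tau))
        total = metrics.ConfusionCounts(0, 0, 0, 0)
        for marg, truth in chains:
            total = total + metrics.confusion(apply_scheme(marg, cfg), truth)
        sn, sp, _ = metrics.basic_rates(total)
        sw = metrics.sw(total) if total.nd > 0 and total.no > 0 else None
        rows.append(
            {
                "tau": float(tau),
                "TP": total.tp,
                "FP": total.fp,
                "TN": total.tn,
                "FN": total.fn,
                "Sn": sn,
                "Sp": sp,
                "Sw": sw,
            }
        )
    table = pd.DataFrame(rows)
    if table["Sw"].notna().any():
        best = table.loc[table["Sw"].idxmax(), "tau"]  # idxmax -> first (smallest tau)
    else:
        best = float(grid[0])
    return table, float(best)


def write_sweep_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
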