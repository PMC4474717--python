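"""Linear-chain conditional random field over the {O, N, D} label set.

The model defines P(y | x) for a chain of length L with per-position
real-valued feature vectors x_p (here: the 12 MCS + secondary-structure
columns, windowed over offsets -4..+4 plus a bias).  Potentials are linear
in the features:

    score(y) = sum_p  w[y_p] . phi(x, p)  +  sum_p  T[y_{p-1}, y_p]

where phi stacks the windowed feature columns (zero-padded outside the
chain) and a constant 1.  Training maximizes the L2-regularized conditional
log-likelihood with L-BFGS; the gradient is the classic observed-minus-
expected feature count, with expectations from forward-backward.  All chain
recursions run in the log domain.

The unigram window template follows the idea of traversing every feature
column at each of four upstream and four downstream neighbours plus the
position itself; transitions are plain label-pair weights with no feature
conditioning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .annotation import STATES
from .features import N_FEATURES, FeatureMatrix

_LABEL_INDEX = {s: i for i, s in enumerate(STATES)}
N_LABELS = len(STATES)

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class TemplateSpec:
    """Window offsets used to expand per-position features."""

    offsets: tuple[int, ...] = (-4, -3, -2, -1, 0, 1, 2, 3, 4)

    def __post_init__(self) -> None:
        if 0 not in self.offsets:
            raise ValueError("template offsets must contain 0")
        if len(set(self.offsets)) != len(self.offsets):
            raise ValueError("template offsets must be distinct")

    @property
    def n_expanded(self) -> int:
        return N_FEATURES * len(self.offsets) + 1  # + bias


@dataclass
class TrainConfig:
    """Optimizer settings for conditional-likelihood training."""

    sigma2: float = 10.0
    max_iter: int = 200
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma2 <= 0 or self.tol <= 0 or self.max_iter < 0:
            raise ValueError("sigma2 and tol must be positive, max_iter >= 0")


@dataclass
class CRFModel:
    """Weights of the chain model: per-label state weights and 3x3 transitions."""

    state_weights: np.ndarray  # (3, n_expanded)
    transitions: np.ndarray  # (3, 3)
    template: TemplateSpec = field(default_factory=TemplateSpec)
    sigma2: float = 10.0
    labels: tuple[str, ...] = STATES

    @classmethod
    def zeros(cls, template: TemplateSpec | None = None, sigma2: float = 10.0) -> "CRFModel":
        template = template or TemplateSpec()
        return cls(
            state_weights=np.zeros((N_LABELS, template.n_expanded)),
            transitions=np.zeros((N_LABELS, N_LABELS)),
            template=template,
            sigma2=sigma2,
        )

    def __post_init__(self) -> None:
        if self.state_weights.shape != (N_LABELS, self.template.n_expanded):
            raise ValueError("state weight shape does not match template")
        if self.transitions.shape != (N_LABELS, N_LABELS):
            raise ValueError("transition matrix must be 3x3")
        if not (np.isfinite(self.state_weights).all() and np.isfinite(self.transitions).all()):
            raise ValueError("weights must be finite")


@dataclass(frozen=True)
class Marginals:
    """Posterior per-position label probabilities, columns (O, N, D)."""

    values: np.ndarray  # (L, 3), rows sum to 1


def expand_features(fm: FeatureMatrix, template: TemplateSpec | None = None) -> np.ndarray:
    """Expand an L x 12 matrix into L windowed vectors of length 12*|offsets| + 1.

    Entry (column c, offset o) at position p is fm[p+o, c] when p+o lies in
    the chain, else 0 (zero padding); the final entry is a constant bias 1.
    """
    template = template or TemplateSpec()
    x = fm.values
    length = x.shape[0]
    out = np.zeros((length, template.n_expanded))
    for k, off in enumerate(template.offsets):
        lo = max(0, -off)
        hi = min(length, length - off)
        if hi > lo:
            out[lo:hi, k * N_FEATURES : (k + 1) * N_FEATURES] = x[lo + off : hi + off]
    out[:, -1] = 1.0
    return out


def _log_norm(v: np.ndarray) -> float:
    m = float(v.max())
    return m + float(np.log(np.exp(v - m).sum()))


def _chain_scores(model: CRFModel, expanded: np.ndarray) -> np.ndarray:
    if expanded.shape[1] != model.template.n_expanded:
        raise ValueError(
            f"expanded feature width {expanded.shape[1]} does not match "
            f"template width {model.template.n_expanded}"
        )
    return expanded @ model.state_weights.T  # (L, 3)


def forward_backward(
    model: CRFModel, expanded: np.ndarray
) -> tuple[float, Marginals, np.ndarray]:
    """Run the forward and backward recursions in the log domain.

    Returns (logZ, posterior marginals, pairwise posteriors).  The pairwise
    array has shape (L-1, 3, 3): entry (p, a, b) is P(y_p = a, y_{p+1} = b).
    The log-partition from the forward and backward directions agree to
    floating-point accuracy; the forward value is returned.
    """
    scores = _chain_scores(model, expanded)
    trans = model.transitions
    length = scores.shape[0]
    alpha = np.zeros((length, N_LABELS))
    beta = np.zeros((length, N_LABELS))
    alpha[0] = scores[0]
    for p in range(1, length):
        v = alpha[p - 1][:, None] + trans  # (3, 3)
        m = v.max(axis=0)
        alpha[p] = scores[p] + m + np.log(np.exp(v - m).sum(axis=0))
    for p in range(length - 2, -1, -1):
        v = trans + scores[p + 1][None, :] + beta[p + 1][None, :]
        m = v.max(axis=1)
        beta[p] = m + np.log(np.exp(v - m[:, None]).sum(axis=1))
    log_z = float(_log_norm(alpha[-1]))
    post = np.exp(alpha + beta - log_z)
    post /= post.sum(axis=1, keepdims=True)  # absorb rounding
    if length > 1:
        pair = np.exp(
            alpha[:-1, :, None]
            + trans[None, :, :]
            + scores[1:, None, :]
            + beta[1:, None, :]
            - log_z
        )
    else:
        pair = np.zeros((0, N_LABELS, N_LABELS))
    return log_z, Marginals(post), pair


def backward_log_z(model: CRFModel, expanded: np.ndarray) -> float:
    """log-partition computed purely from the backward recursion (for checks)."""
    scores = _chain_scores(model, expanded)
    trans = model.transitions
    length = scores.shape[0]
    beta = np.zeros(N_LABELS)
    for p in range(length - 2, -1, -1):
        v = trans + scores[p + 1][None, :] + beta[None, :]
        m = v.max(axis=1)
        beta = m + np.log(np.exp(v - m[:, None]).sum(axis=1))
    return float(_log_norm(scores[0] + beta))


def viterbi(model: CRFModel, expanded: np.ndarray) -> str:
    """MAP label path; ties break toward the earlier label in (O, N, D)."""
    scores = _chain_scores(model, expanded)
    trans = model.transitions
    length = scores.shape[0]
    delta = scores[0].copy()
    back = np.zeros((length, N_LABELS), dtype=np.int64)
    for p in range(1, length):
        v = delta[:, None] + trans  # (prev, cur)
        back[p] = np.argmax(v, axis=0)  # first max index -> earlier label wins
        delta = scores[p] + v[back[p], np.arange(N_LABELS)]
    path = np.zeros(length, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for p in range(length - 1, 0, -1):
        path[p - 1] = back[p, path[p]]
    return "".join(STATES[i] for i in path)


def path_score(model: CRFModel, expanded: np.ndarray, labels: str) -> float:
    """Unnormalized joint score of one label path (for oracles and training)."""
    scores = _chain_scores(model, expanded)
    idx = np.fromiter((_LABEL_INDEX[c] for c in labels), dtype=np.int64)
    total = float(scores[np.arange(len(idx)), idx].sum())
    if len(idx) > 1:
        total += float(model.transitions[idx[:-1], idx[1:]].sum())
    return total


# ---------------------------------------------------------------------------
# training


def _pack(state_w: np.ndarray, trans: np.ndarray) -> np.ndarray:
    return np.concatenate([state_w.ravel(), trans.ravel()])


def _unpack(w: np.ndarray, n_expanded: int) -> tuple[np.ndarray, np.ndarray]:
    cut = N_LABELS * n_expanded
    return w[:cut].reshape(N_LABELS, n_expanded), w[cut:].reshape(N_LABELS, N_LABELS)


def objective(
    w: np.ndarray,
    dataset: list[tuple[np.ndarray, np.ndarray]],
    template: TemplateSpec,
    sigma2: float,
) -> tuple[float, np.ndarray]:
    """Negative penalized conditional log-likelihood and its gradient.

    ``dataset`` holds (expanded features, integer label index array) pairs.
    The gradient is observed minus expected feature counts, negated, plus
    the L2 term w / sigma2.
    """
    state_w, trans = _unpack(w, template.n_expanded)
    model = CRFModel(state_w, trans, template, sigma2)
    neg_ll = 0.0
    g_state = np.zeros_like(state_w)
    g_trans = np.zeros_like(trans)
    for expanded, y in dataset:
        log_z, marg, pair = forward_backward(model, expanded)
        scores = expanded @ state_w.T
        ll = float(scores[np.arange(len(y)), y].sum())
        if len(y) > 1:
            ll += float(trans[y[:-1], y[1:]].sum())
        ll -= log_z
        neg_ll -= ll
        obs = np.zeros((N_LABELS, expanded.shape[0]))
        obs[y, np.arange(len(y))] = 1.0
        g_state -= (obs - marg.values.T) @ expanded
        if len(y) > 1:
            obs_pair = np.zeros_like(trans)
            np.add.at(obs_pair, (y[:-1], y[1:]), 1.0)
            g_trans -= obs_pair - pair.sum(axis=0)
    penalty = float(w @ w) / (2.0 * sigma2)
    grad = _pack(g_state, g_trans) + w / sigma2
    return neg_ll + penalty, grad


def train(
    dataset: list[tuple[FeatureMatrix, str]],
    config: TrainConfig | None = None,
    template: TemplateSpec | None = None,
) -> tuple[CRFModel, dict]:
    """Fit the CRF by L-BFGS on the regularized conditional likelihood.

    Initialization is all-zeros, so training is deterministic; the returned
    log records the penalized log-likelihood trajectory over accepted
    iterates (non-decreasing by line-search construction).
    """
    config = config or TrainConfig()
    template = template or TemplateSpec()
    if not dataset:
        raise ValueError("empty training set")
    prepared: list[tuple[np.ndarray, np.ndarray]] = []
    for fm, labels in dataset:
        if len(fm) != len(labels):
            raise ValueError("feature/label length mismatch")
        y = np.fromiter((_LABEL_INDEX[c] for c in labels), dtype=np.int64)
        prepared.append((expand_features(fm, template), y))

    w0 = np.zeros(N_LABELS * template.n_expanded + N_LABELS * N_LABELS)
    trajectory: list[float] = []
    if config.max_iter == 0:
        model = CRFModel.zeros(template, config.sigma2)
        return model, {"objective_trajectory": [], "n_iter": 0}

    def record(wk: np.ndarray) -> None:
        f, _ = objective(wk, prepared, template, config.sigma2)
        trajectory.append(-f)  # penalized log-likelihood

    res = minimize(
        objective,
        w0,
        args=(prepared, template, config.sigma2),
        jac=True,
        method="L-BFGS-B",
        callback=record,
        options={"maxiter": config.max_iter, "ftol": config.tol, "gtol": 1e-8},
    )
    state_w, trans = _unpack(res.x, template.n_expanded)
    model = CRFModel(state_w, trans, template, config.sigma2)
    log = {
        "objective_trajectory": trajectory,
        "n_iter": int(res.nit),
        "converged": bool(res.success),
        "final_objective": float(-res.fun),
    }
    return model, log


def predict_marginals(model: CRFModel, fm: FeatureMatrix) -> Marginals:
    """Posterior marginals for one chain's feature matrix."""
    _, marg, _ = forward_backward(model, expand_features(fm, model.template))
    return marg


def predict_path(model: CRFModel, fm: FeatureMatrix) -> str:
    """Viterbi path for one chain's feature matrix."""
    return viterbi(model, expand_features(fm, model.template))


# ---------------------------------------------------------------------------
# serialization: versioned portable JSON, bit-exact round trip


def save_model(model: CRFModel, path) -> None:
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "labels": list(model.labels),
        "offsets": list(model.template.offsets),
        "sigma2": model.sigma2,
        "state_weights": [[float(v) for v in row] for row in model.state_weights],
        "transitions": [[float(v) for v in row] for row in model.transitions],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> CRFModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {doc.get('format_version')!r}")
    if tuple(doc["labels"]) != STATES:
        raise ValueError("model label set does not match (O, N, D)")
    template = TemplateSpec(tuple(doc["offsets"]))
    return CRFModel(
        state_weights=np.array(doc["state_weights"], dtype=np.float64),
        transitions=np.array(doc["transitions"], dtype=np.float64),
        template=template,
        sigma2=float(doc["sigma2"]),
    )
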