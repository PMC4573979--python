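"""Statistical validation of PLS-DA models: R2Y, Q2Y via PRESS, and
response permutation testing.

Q2Y is the cross-validated analogue of R2Y:

    PRESS = sum_i (y_i - yhat_i^{held-out})^2
    SS    = sum_i (y_i - ybar)^2
    Q2Y   = 1 - PRESS / SS

computed over stratified k-fold partitions with the model refitted on
each training part.  The permutation test refits the model (same CV
scheme, fixed component count) after randomly reordering the class
labels while leaving the antigen profiles intact; the empirical p-value
uses the add-one rule  p = (1 + #{null >= observed}) / (N + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .plsda import DegenerateDataError, _autoscale, _code_response


@dataclass(frozen=True)
class ValidationConfig:
    k_folds: int = 10
    max_components: int = 5
    n_permutations: int = 1000
    seed: int = 0
    # parsimony tolerance: the chosen A is the smallest component count
    # whose Q2Y is within this margin of the maximum (near-ties go to the
    # simpler model)
    q2_tolerance: float = 0.01

    def __post_init__(self):
        if self.k_folds < 2:
            raise ValueError("need k >= 2 folds")
        if self.n_permutations < 1:
            raise ValueError("need N >= 1 permutations")


@dataclass
class CVResult:
    per_component: pd.DataFrame   # columns: A, R2Y, PRESS, Q2Y
    ss: float
    chosen_a: int

    @property
    def q2y(self) -> float:
        return float(
            self.per_component.set_index("A").loc[self.chosen_a, "Q2Y"]
        )

    @property
    def r2y(self) -> float:
        return float(
            self.per_component.set_index("A").loc[self.chosen_a, "R2Y"]
        )


@dataclass
class PermutationResult:
    observed_r2y: float
    observed_q2y: float
    null_r2y: np.ndarray
    null_q2y: np.ndarray
    p_r2y: float
    p_q2y: float
    n_components: int
    extra: dict = field(default_factory=dict)


def _pls1_core(Xc: np.ndarray, yc: np.ndarray, a_max: int):
    """Lean NIPALS PLS1 on pre-centered data; returns (W, P, q, n_extracted)."""
    n, p = Xc.shape
    a_max = min(a_max, n - 1, p)
    W = np.empty((p, a_max))
    P = np.empty((p, a_max))
    q = np.empty(a_max)
    Xd = Xc.copy()
    yd = yc.copy()
    y_norm = max(1.0, float(np.linalg.norm(yc)))
    a = 0
    while a < a_max:
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw <= 1e-12 * y_norm:
            break
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt <= 0:
            break
        pa = Xd.T @ t / tt
        qa = float(yd @ t) / tt
        Xd -= np.outer(t, pa)
        yd -= qa * t
        W[:, a], P[:, a], q[a] = w, pa, qa
        a += 1
    return W[:, :a], P[:, :a], q[:a], a


def _coef_paths(W, P, q) -> np.ndarray:
    """Regression vectors for every component prefix (p x A)."""
    a = W.shape[1]
    out = np.empty((W.shape[0], a))
    PtW = P.T @ W
    for j in range(1, a + 1):
        out[:, j - 1] = W[:, :j] @ np.linalg.solve(PtW[:j, :j], q[:j])
    return out


def _cv_curves(
    X: np.ndarray, y01: np.ndarray, k: int, a_max: int, fold_seed: int
) -> tuple[np.ndarray, np.ndarray, float]:
    """(R2Y per A, Q2Y per A, SS) with stratified k-fold held-out PRESS.

    If the data exhaust before ``a_max`` components in some fit, the last
    available prediction is carried forward for the larger A values.
    """
    n = len(y01)
    counts = np.bincount(y01.astype(int))
    if counts.min() < k:
        raise DegenerateDataError(
            f"stratified {k}-fold CV impossible: smallest class has "
            f"{counts.min()} samples"
        )
    ybar = y01.mean()
    ss = float(((y01 - ybar) ** 2).sum())

    # full-data fit -> R2Y per component count
    Xs, _, _ = _autoscale(X)
    yc = y01 - ybar
    W, P, q, a_fit = _pls1_core(Xs, yc, a_max)
    if a_fit == 0:
        raise DegenerateDataError("no PLS component extractable from the data")
    B = _coef_paths(W, P, q)
    fitted = Xs @ B + ybar                     # n x a_fit
    if a_fit < a_max:
        fitted = np.hstack([fitted, np.tile(fitted[:, -1:], a_max - a_fit)])
    r2 = 1.0 - ((y01[:, None] - fitted) ** 2).sum(axis=0) / ss

    preds = np.empty((n, a_max))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=fold_seed)
    for train, test in skf.split(X, y01):
        Xtr = X[train]
        mean = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        ytr = y01[train]
        ytr_bar = ytr.mean()
        Wf, Pf, qf, af = _pls1_core((Xtr - mean) / sd, ytr - ytr_bar, a_max)
        if af == 0:
            preds[test] = ytr_bar
            continue
        Bf = _coef_paths(Wf, Pf, qf)
        ph = ((X[test] - mean) / sd) @ Bf + ytr_bar
        if af < a_max:
            ph = np.hstack([ph, np.tile(ph[:, -1:], a_max - af)])
        preds[test] = ph
    press = ((y01[:, None] - preds) ** 2).sum(axis=0)
    q2 = 1.0 - press / ss
    return r2, q2, ss


def cross_validate(
    X, y, cfg: ValidationConfig, positive_label=None
) -> CVResult:
    """R2Y / PRESS / Q2Y for A = 1..max_components; the chosen component
    count maximizes Q2Y, with near-ties (within ``q2_tolerance``) broken
    toward the simpler model."""
    X = np.asarray(X, dtype=float) if not isinstance(X, pd.DataFrame) else X.to_numpy(dtype=float)
    y01, _ = _code_response(np.asarray(y), positive_label)
    a_max = min(cfg.max_components, X.shape[0] - 1, X.shape[1])
    r2, q2, ss = _cv_curves(X, y01, cfg.k_folds, a_max, fold_seed=cfg.seed)
    press = (1.0 - q2) * ss
    table = pd.DataFrame(
        {"A": np.arange(1, a_max + 1), "R2Y": r2, "PRESS": press, "Q2Y": q2}
    )
    chosen = int(np.argmax(q2 >= q2.max() - cfg.q2_tolerance)) + 1
    return CVResult(per_component=table, ss=ss, chosen_a=chosen)


def permutation_test(
    X, y, cfg: ValidationConfig, n_components: int, positive_label=None
) -> PermutationResult:
    """Response-permutation null distributions of R2Y and Q2Y at fixed A."""
    X = np.asarray(X, dtype=float) if not isinstance(X, pd.DataFrame) else X.to_numpy(dtype=float)
    y01, _ = _code_response(np.asarray(y), positive_label)
    rng = np.random.default_rng(cfg.seed)

    def stats(labels: np.ndarray, fold_seed: int) -> tuple[float, float]:
        r2, q2, _ = _cv_curves(X, labels, cfg.k_folds, n_components, fold_seed)
        return float(r2[-1]), float(q2[-1])

    obs_r2, obs_q2 = stats(y01, fold_seed=int(rng.integers(2**31)))
    null_r2 = np.empty(cfg.n_permutations)
    null_q2 = np.empty(cfg.n_permutations)
    for i in range(cfg.n_permutations):
        yp = rng.permutation(y01)
        null_r2[i], null_q2[i] = stats(yp, fold_seed=int(rng.integers(2**31)))
    p_r2 = (1.0 + (null_r2 >= obs_r2).sum()) / (cfg.n_permutations + 1.0)
    p_q2 = (1.0 + (null_q2 >= obs_q2).sum()) / (cfg.n_permutations + 1.0)
    return PermutationResult(
        observed_r2y=obs_r2, observed_q2y=obs_q2,
        null_r2y=null_r2, null_q2y=null_q2,
        p_r2y=float(p_r2), p_q2y=float(p_q2),
        n_components=n_components,
    )
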