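"""PLS-DA with VIP scores, and the recursive-SVM comparator ranking.

PLS-DA is fitted by sequential NIPALS extraction on autoscaled X
(centered, unit variance) against a centered 0/1 class code.  For a
univariate response each component reduces to

    w_a = X_a' y_a / ||X_a' y_a||      (unit-norm weight)
    t_a = X_a w_a                      (score)
    p_a = X_a' t_a / (t_a' t_a)        (X loading)
    q_a = y_a' t_a / (t_a' t_a)        (Y loading)

with X deflated by t_a p_a' (and y by q_a t_a).  The explained-response
sum of squares of component a is SS_a = q_a^2 (t_a' t_a), and the
variable importance in projection is

    VIP_j = sqrt( p * sum_a SS_a w_aj^2 / sum_a SS_a ),

whose squared values average to one; the conventional "VIP > 1" rule
marks the variables with above-average influence on the class separation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class DegenerateDataError(ValueError):
    """Raised when the data cannot support the requested model."""


def _autoscale(X: np.ndarray):
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mean) / sd, mean, sd


def _code_response(y: np.ndarray, positive_label=None):
    labels = np.unique(y)
    if len(labels) != 2:
        raise DegenerateDataError(
            f"exactly two classes required, got {len(labels)}"
        )
    if positive_label is None:
        positive_label = labels[1]
    return (np.asarray(y) == positive_label).astype(float), positive_label


@dataclass
class PLSModel:
    """Fitted PLS-DA model (univariate class response)."""

    n_components: int
    weights: np.ndarray      # p x A, unit-norm columns
    x_loadings: np.ndarray   # p x A
    y_loadings: np.ndarray   # A
    scores: np.ndarray       # n x A
    ss_y: np.ndarray         # A, explained response SS per component
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    positive_label: object
    feature_names: list[str]

    def coefficients(self, n_components: int | None = None) -> np.ndarray:
        """Regression vector on the autoscaled X for the leading
        ``n_components`` components: B = W (P'W)^{-1} q."""
        a = self.n_components if n_components is None else n_components
        if not 1 <= a <= self.n_components:
            raise ValueError("invalid component count")
        W, P, q = self.weights[:, :a], self.x_loadings[:, :a], self.y_loadings[:a]
        return W @ np.linalg.solve(P.T @ W, q)

    def predict(self, X, n_components: int | None = None) -> np.ndarray:
        """Continuous class-code prediction (0/1 scale)."""
        X = np.asarray(X, dtype=float)
        Xs = (X - self.x_mean) / self.x_scale
        return self.y_mean + Xs @ self.coefficients(n_components)

    def r2y(self, X, y, n_components: int | None = None) -> float:
        y01, _ = _code_response(np.asarray(y), self.positive_label)
        resid = y01 - self.predict(X, n_components)
        ss = ((y01 - y01.mean()) ** 2).sum()
        return 1.0 - float((resid**2).sum()) / ss

    @property
    def vip(self) -> pd.Series:
        return pd.Series(vip_scores(self), index=self.feature_names, name="vip")


def fit_plsda(
    X, y, n_components: int, scale: bool = True, positive_label=None,
    feature_names: list[str] | None = None,
) -> PLSModel:
    """NIPALS PLS-DA on autoscaled X and a centered 0/1 class code."""
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns) if feature_names is None else feature_names
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if feature_names is None:
        feature_names = [str(j) for j in range(p)]
    y01, pos = _code_response(np.asarray(y), positive_label)
    if len(y01) != n:
        raise ValueError("X and y length mismatch")
    a_max = min(n - 1, p)
    if not 1 <= n_components <= a_max:
        raise DegenerateDataError(
            f"n_components must be in [1, {a_max}] for this data"
        )
    if scale:
        Xs, x_mean, x_scale = _autoscale(X)
    else:
        x_mean = X.mean(axis=0)
        x_scale = np.ones(p)
        Xs = X - x_mean
    y_mean = float(y01.mean())
    yd = y01 - y_mean

    W = np.empty((p, n_components))
    P = np.empty((p, n_components))
    q = np.empty(n_components)
    T = np.empty((n, n_components))
    ss_y = np.empty(n_components)
    Xd = Xs.copy()
    for a in range(n_components):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw <= 1e-12 * max(1.0, np.linalg.norm(yd)) or nw == 0.0:
            raise DegenerateDataError(
                f"cannot extract component {a + 1}: response already exhausted"
            )
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt <= 0:
            raise DegenerateDataError(f"degenerate score in component {a + 1}")
        pa = Xd.T @ t / tt
        qa = float(yd @ t) / tt
        Xd -= np.outer(t, pa)
        yd = yd - qa * t
        W[:, a], P[:, a], q[a], T[:, a] = w, pa, qa, t
        ss_y[a] = qa**2 * tt
    return PLSModel(
        n_components=n_components, weights=W, x_loadings=P, y_loadings=q,
        scores=T, ss_y=ss_y, x_mean=x_mean, x_scale=x_scale, y_mean=y_mean,
        positive_label=pos, feature_names=feature_names,
    )


def vip_scores(model: PLSModel) -> np.ndarray:
    """Wold VIP: sqrt(p * sum_a SS_a w_aj^2 / sum_a SS_a)."""
    ss = model.ss_y
    total = ss.sum()
    if total <= 0:
        raise DegenerateDataError("all components explain zero response variance")
    p = model.weights.shape[0]
    return np.sqrt(p * (model.weights**2 @ ss) / total)


def vip_feature_set(vip: pd.Series, vip_min: float = 1.0) -> set[str]:
    """The strictly-above-threshold feature set {j : VIP_j > vip_min}."""
    return set(vip.index[vip > vip_min])


# ---------------------------------------------------------------------------
# Recursive SVM comparator
# ---------------------------------------------------------------------------

def rsvm_rank(
    X, y, elimination_fraction: float = 0.5, C: float = 1.0,
    scale: bool = True, positive_label=None,
) -> pd.DataFrame:
    """Recursive feature elimination with a linear maximum-margin classifier.

    At each round a linear SVM (fixed C) is trained on the surviving
    features; each feature is scored by its weighted class-mean
    contribution  s_j = w_j (mean_{+,j} - mean_{-,j})  and the
    lowest-scoring fraction is eliminated.  The final ranking is the
    reverse elimination order (rank 1 = eliminated last).
    """
    from sklearn.svm import SVC

    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        names = [str(j) for j in range(X.shape[1])]
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least 2 features")
    if not 0 < elimination_fraction < 1:
        raise ValueError("elimination fraction must be in (0, 1)")
    y01, pos = _code_response(np.asarray(y), positive_label)
    if scale:
        X, _, _ = _autoscale(X)
    mean_diff = X[y01 == 1].mean(axis=0) - X[y01 == 0].mean(axis=0)

    surviving = list(range(p))
    elimination_order: list[int] = []  # first = worst
    first_round = True
    while len(surviving) > 1:
        svc = SVC(kernel="linear", C=C)
        svc.fit(X[:, surviving], y01)
        w = svc.coef_[0]
        if svc.classes_[0] == 1.0:  # pragma: no cover - sklearn sorts classes
            w = -w
        s = w * mean_diff[surviving]
        if first_round:
            if np.allclose(s, 0.0):
                raise DegenerateDataError(
                    "identical classes: zero separation in every feature"
                )
            first_round = False
        n_elim = max(1, int(np.floor(len(surviving) * elimination_fraction)))
        n_elim = min(n_elim, len(surviving) - 1)
        # lowest score eliminated first; ties broken by feature index (stable)
        order = sorted(range(len(surviving)), key=lambda i: (s[i], surviving[i]))
        drop = [surviving[i] for i in order[:n_elim]]
        elimination_order.extend(drop)
        surviving = [j for j in surviving if j not in set(drop)]
    elimination_order.extend(surviving)

    ranked = list(reversed(elimination_order))  # best first
    return pd.DataFrame(
        {
            "antigen_id": [names[j] for j in ranked],
            "rank": np.arange(1, p + 1),
            "score": np.arange(p, 0, -1, dtype=float),
            "ranker": "R-SVM",
        }
    )


def top_k_features(ranked: pd.DataFrame, k: int) -> set[str]:
    """Top-k feature set of a ranked list (k matched to a PLS-DA VIP set
    size when comparing stability across rankers)."""
    if k > len(ranked):
        raise ValueError(f"k={k} exceeds the number of ranked features")
    return set(ranked.nsmallest(k, "rank")["antigen_id"])
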