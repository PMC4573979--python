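"""Balanced discovery subsets and PCA-based sample outlier screening.

The discovery cohort is heavily imbalanced (e.g. 15 AIH vs 78 HD), so
modelling proceeds on an ensemble of R balanced subsets: every subset
keeps the whole minority class and draws a fixed-size majority subset
without replacement under an exact female:male ratio constraint (3:1 by
default, i.e. 18 F + 6 M when the majority subset size is 24).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist


@dataclass(frozen=True)
class EnsembleConfig:
    r: int = 50                    # number of balanced subsets
    minority_group: str = "AIH"
    majority_group: str = "HD"
    n_majority: int = 24           # majority samples per subset
    female_ratio: float = 0.75     # fraction of majority draw that is female
    seed: int = 0

    def __post_init__(self):
        if self.r < 2:
            raise ValueError("need at least 2 subsets")
        if self.n_majority < 2:
            raise ValueError("majority subset size must be >= 2")

    @property
    def n_female(self) -> int:
        return int(round(self.n_majority * self.female_ratio))

    @property
    def n_male(self) -> int:
        return self.n_majority - self.n_female


@dataclass
class SubsetEnsemble:
    subsets: list[list[str]]       # each = all minority ids + sampled majority ids
    minority_ids: list[str]
    config: EnsembleConfig
    subset_seeds: list[int] = field(default_factory=list)


def balanced_subsets(samples: pd.DataFrame, cfg: EnsembleConfig) -> SubsetEnsemble:
    """R balanced subsets under the exact sex-ratio constraint.

    Each subset holds every minority-class sample plus ``n_majority``
    majority samples (``n_female`` females, ``n_male`` males) sampled
    without replacement; the ensemble is seeded and reproducible.
    """
    minority = samples.loc[samples["group"] == cfg.minority_group, "sample_id"]
    if minority.empty:
        raise ValueError(f"no samples in minority group {cfg.minority_group!r}")
    maj = samples[samples["group"] == cfg.majority_group]
    fem = maj.loc[maj["sex"] == "F", "sample_id"].to_numpy()
    mal = maj.loc[maj["sex"] == "M", "sample_id"].to_numpy()
    if len(fem) < cfg.n_female:
        raise ValueError(
            f"insufficient {cfg.majority_group} females: need {cfg.n_female}, "
            f"have {len(fem)}"
        )
    if len(mal) < cfg.n_male:
        raise ValueError(
            f"insufficient {cfg.majority_group} males: need {cfg.n_male}, "
            f"have {len(mal)}"
        )
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.r)
    subsets, seeds = [], []
    minority_ids = minority.tolist()
    for child in children:
        rng = np.random.default_rng(child)
        pick_f = rng.choice(fem, size=cfg.n_female, replace=False)
        pick_m = rng.choice(mal, size=cfg.n_male, replace=False)
        subsets.append(minority_ids + sorted(pick_f) + sorted(pick_m))
        seeds.append(int(child.generate_state(1)[0] % 2**31))
    return SubsetEnsemble(
        subsets=subsets, minority_ids=minority_ids, config=cfg, subset_seeds=seeds
    )


@dataclass
class OutlierScreen:
    flags: pd.Series          # bool per sample
    t2: pd.Series             # Hotelling T^2 per sample
    cutoff: float
    scores: pd.DataFrame      # sample x component PCA scores
    n_components: int
    alpha: float


def pca_outlier_screen(
    matrix: pd.DataFrame, n_components: int = 2, alpha: float = 0.01,
    scale: bool = True,
) -> OutlierScreen:
    """Flag atypical samples by Hotelling T^2 over leading PCA scores.

    Data are centered (and unit-variance scaled by default); a sample is
    flagged when its T^2 over the first ``n_components`` scores exceeds
    the F cutoff  T2 > K (n-1) / (n-K) * F_{1-a}(K, n-K), with a =
    alpha / n (Bonferroni), so ``alpha`` is the familywise false-alarm
    level of screening the whole cohort.
    """
    X = matrix.to_numpy(dtype=float)
    n, p = X.shape
    if n_components >= n:
        raise ValueError("n_components must be < n_samples")
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    if not np.any(X):
        raise ValueError("constant matrix: PCA undefined")
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    k = n_components
    scores = u[:, :k] * s[:k]
    lam = s[:k] ** 2 / (n - 1)
    t2 = (scores**2 / lam).sum(axis=1)
    cutoff = k * (n - 1) / (n - k) * f_dist.ppf(1 - alpha / n, k, n - k)
    flags = pd.Series(t2 > cutoff, index=matrix.index)
    return OutlierScreen(
        flags=flags,
        t2=pd.Series(t2, index=matrix.index),
        cutoff=float(cutoff),
        scores=pd.DataFrame(
            scores, index=matrix.index, columns=[f"PC{i+1}" for i in range(k)]
        ),
        n_components=k,
        alpha=alpha,
    )
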