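"""Validation-phase plate immunoassay (DELFIA) analytics.

Positivity: a serum is positive for a marker when its duplicate-averaged
fluorescence strictly exceeds the healthy-donor mean plus one standard
error of the mean (SEM = SD / sqrt(n)).  Group comparisons use the
chi-square test on the 2x2 call table (Fisher's exact test when any
expected count is below 5) and Student's t test on intensities.  ROC
curves are empirical staircases over all distinct cut-offs; AUC is the
trapezoid area (equal to the rank-sum probability estimate, ties counted
half); the best cut-off maximizes Youden's J = SE + SP - 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .stability import round_half_up


@dataclass(frozen=True)
class DelfiaThreshold:
    marker: str
    hd_mean: float
    hd_sem: float

    @property
    def value(self) -> float:
        return self.hd_mean + self.hd_sem


def average_duplicates(plate: pd.DataFrame) -> pd.DataFrame:
    """Long well-level table -> sample x marker matrix of duplicate means."""
    return plate.pivot_table(
        index="sample_id", columns="marker", values="fluorescence", aggfunc="mean"
    )


def delfia_positivity(
    values: pd.Series, hd_values: np.ndarray, marker: str = ""
) -> tuple[pd.Series, DelfiaThreshold]:
    """Calls (1 iff value > HD mean + 1 SEM) and the threshold used."""
    hd = np.asarray(hd_values, dtype=float)
    if len(hd) < 2:
        raise ValueError("need >= 2 healthy-donor values")
    thr = DelfiaThreshold(
        marker=marker,
        hd_mean=float(hd.mean()),
        hd_sem=float(hd.std(ddof=1) / np.sqrt(len(hd))),
    )
    calls = (values > thr.value).astype(np.int8)
    return calls, thr


def sens_spec(
    calls: pd.Series, labels: pd.Series, positive_group: str, control_group: str
) -> tuple[float, float]:
    """(sensitivity %, specificity %) — exact values, not rounded."""
    pos = labels == positive_group
    neg = labels == control_group
    if not pos.any() or not neg.any():
        raise ValueError("both groups must be non-empty")
    se = 100.0 * float(calls[pos].sum()) / int(pos.sum())
    sp = 100.0 * float((1 - calls[neg]).sum()) / int(neg.sum())
    return se, sp


def significance_stars(p: float) -> str:
    if p < 1e-4:
        return "***"
    if p < 1e-3:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def group_tests(
    values: pd.Series, calls: pd.Series, labels: pd.Series,
    groups: tuple[str, str], continuity_correction: bool = False,
    call_test: str = "auto",
) -> dict:
    """Call-table test and intensity t test.

    ``call_test``: "chi2", "fisher", or "auto" (chi-square with a Fisher
    fallback whenever an expected cell count is below 5).
    """
    g1, g2 = groups
    m1, m2 = labels == g1, labels == g2
    if not m1.any() or not m2.any():
        raise ValueError("both groups must be non-empty")
    table = np.array(
        [
            [int(calls[m1].sum()), int((1 - calls[m1]).sum())],
            [int(calls[m2].sum()), int((1 - calls[m2]).sum())],
        ]
    )
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    if call_test == "auto":
        call_test = "fisher" if (expected < 5).any() else "chi2"
    if call_test == "fisher":
        _, p_calls = stats.fisher_exact(table, alternative="two-sided")
    elif call_test == "chi2":
        _, p_calls, _, _ = stats.chi2_contingency(
            table, correction=continuity_correction
        )
    else:
        raise ValueError(f"unknown call test {call_test!r}")
    t_res = stats.ttest_ind(values[m1], values[m2], equal_var=True)
    return {
        "table": table,
        "call_test": call_test,
        "p_calls": float(p_calls),
        "p_intensity": float(t_res.pvalue),
        "stars_calls": significance_stars(float(p_calls)),
        "stars_intensity": significance_stars(float(t_res.pvalue)),
    }


@dataclass
class ROCResult:
    curve: pd.DataFrame       # cutoff, tpr (SE), fpr (1-SP), monotone staircase
    auc: float
    best_cutoff: float
    best_se: float            # %
    best_sp: float            # %
    control_definition: str = ""


def roc_auc(scores, labels, positive=1, control_definition: str = "") -> ROCResult:
    """Empirical ROC over all distinct cut-offs (call positive when score
    >= cutoff); AUC by trapezoid; best cut-off by Youden J, ties resolved
    toward the higher specificity."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = y == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-s, kind="stable")
    s_sorted, pos_sorted = s[order], pos[order]
    distinct = np.r_[np.diff(s_sorted) != 0, True]  # last of each tie block
    tp = np.cumsum(pos_sorted)[distinct]
    fp = np.cumsum(~pos_sorted)[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    cutoffs = np.r_[np.inf, s_sorted[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    best = max(range(len(j)), key=lambda i: (j[i], -fpr[i]))
    return ROCResult(
        curve=pd.DataFrame({"cutoff": cutoffs, "tpr": tpr, "fpr": fpr}),
        auc=auc,
        best_cutoff=float(cutoffs[best]),
        best_se=float(100.0 * tpr[best]),
        best_sp=float(100.0 * (1.0 - fpr[best])),
        control_definition=control_definition,
    )


def combine_markers(
    data: pd.DataFrame, markers: list[str], mode: str = "or-rule",
    calls: pd.DataFrame | None = None, hd_mask: pd.Series | None = None,
) -> pd.Series:
    """Combine a marker panel into one call or score vector.

    ``or-rule``: combined call positive iff any member marker's call is
    positive (frequency-style panel sensitivity/specificity).
    ``score-sum``: per-marker z-score against the healthy-donor reference
    (``hd_mask``), summed; intended as a continuous score for ROC.
    """
    missing = [m for m in markers if m not in data.columns]
    if missing:
        raise ValueError(f"unknown markers: {missing}")
    if mode == "or-rule":
        if calls is None:
            raise ValueError("or-rule combination requires the call matrix")
        return calls[markers].max(axis=1).astype(np.int8)
    if mode == "score-sum":
        if hd_mask is None:
            raise ValueError("score-sum combination requires the HD mask")
        hd = data.loc[hd_mask.reindex(data.index, fill_value=False), markers]
        z = (data[markers] - hd.mean()) / hd.std(ddof=1)
        return z.sum(axis=1)
    raise ValueError(f"unknown combination mode {mode!r}")
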