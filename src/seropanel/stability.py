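"""Feature-selection stability (Tanimoto index) and the multicriteria
consensus panel.

Stability of a ranker over the balanced-subset ensemble is the mean
pairwise Tanimoto similarity |A∩B| / |A∪B| between its per-subset
selected-feature sets.  The consensus autoantigen panel applies three
filters jointly:

1. VIP > 1 in *every* subset (relative frequency of 100% across the
   ensemble);
2. recognized by fewer than 25% of control (HD) sera;
3. recognized by more than 50% of disease (AIH) sera,

with recognition frequencies computed on the full (post-outlier-
exclusion) discovery cohort.  All threshold comparisons are strict.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding as used in report tables (86.67 -> 87)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def tanimoto(a: set, b: set) -> float:
    """|a ∩ b| / |a ∪ b|; two empty sets are identical (similarity 1)."""
    union = len(a | b)
    if union == 0:
        return 1.0
    return len(a & b) / union


@dataclass
class StabilityResult:
    ranker: str
    matrix: pd.DataFrame     # R x R pairwise Tanimoto similarities
    average: float           # mean over the R(R-1)/2 distinct pairs


def stability_matrix(feature_sets: list[set], ranker: str = "") -> StabilityResult:
    """All pairwise Tanimoto similarities; the average excludes the diagonal."""
    r = len(feature_sets)
    if r < 2:
        raise ValueError("need at least 2 feature sets")
    m = np.ones((r, r))
    pairs = []
    for i in range(r):
        for j in range(i + 1, r):
            m[i, j] = m[j, i] = tanimoto(feature_sets[i], feature_sets[j])
            pairs.append(m[i, j])
    labels = [f"subset{i:02d}" for i in range(r)]
    return StabilityResult(
        ranker=ranker,
        matrix=pd.DataFrame(m, index=labels, columns=labels),
        average=float(np.mean(pairs)),
    )


def recognition_frequency(
    positivity: pd.DataFrame, samples: pd.DataFrame, group: str
) -> pd.Series:
    """Per antigen, the exact percentage of the group's sera calling it
    positive (rounding to whole percent is left to report formatting)."""
    ids = samples.loc[samples["group"] == group, "sample_id"]
    ids = [s for s in ids if s in positivity.index]
    if not ids:
        raise ValueError(f"group {group!r} empty or absent from the matrix")
    sub = positivity.loc[ids]
    return 100.0 * sub.mean(axis=0)


def frequency_table(
    positivity: pd.DataFrame, samples: pd.DataFrame,
    groups: tuple[str, str] = ("HD", "AIH"),
) -> pd.DataFrame:
    """Exact recognition percentages per antigen for the given groups
    (columns ``<group>_pct``)."""
    return pd.DataFrame(
        {f"{g}_pct": recognition_frequency(positivity, samples, g) for g in groups}
    )


@dataclass
class PanelSelection:
    table: pd.DataFrame      # per selected antigen: mean_vip, HD_pct, AIH_pct, rel_freq
    stage_counts: dict       # filter-funnel sizes
    thresholds: dict

    @property
    def antigens(self) -> list[str]:
        return list(self.table.index)


def multicriteria_select(
    vip_by_subset: pd.DataFrame,
    freq: pd.DataFrame,
    vip_min: float = 1.0,
    hd_max_pct: float = 25.0,
    aih_min_pct: float = 50.0,
    rel_freq_min: float = 1.0,
    hd_col: str = "HD_pct",
    aih_col: str = "AIH_pct",
) -> PanelSelection:
    """Consensus panel: VIP > vip_min in every subset (relative frequency
    = 100%), HD% strictly below ``hd_max_pct`` and AIH% strictly above
    ``aih_min_pct``.  Funnel sizes at each stage are reported.
    """
    if vip_by_subset.isna().any().any():
        bad = vip_by_subset.columns[vip_by_subset.isna().any()].tolist()
        raise ValueError(f"missing VIP values for subsets: {bad}")
    antigens = vip_by_subset.index
    freq = freq.reindex(antigens)
    passes = vip_by_subset > vip_min
    rel_freq = passes.mean(axis=1)
    vip_any = passes.any(axis=1)
    freq_ok = (freq[hd_col] < hd_max_pct) & (freq[aih_col] > aih_min_pct)
    consensus = rel_freq >= rel_freq_min
    selected = consensus & freq_ok
    table = pd.DataFrame(
        {
            "mean_vip": vip_by_subset.mean(axis=1),
            hd_col: freq[hd_col],
            aih_col: freq[aih_col],
            "rel_freq": rel_freq,
        }
    ).loc[selected]
    table = table.sort_values("mean_vip", ascending=False)
    return PanelSelection(
        table=table,
        stage_counts={
            "vip_pass_any_subset": int(vip_any.sum()),
            "frequency_pass": int(freq_ok.sum()),
            "vip_and_frequency": int((vip_any & freq_ok).sum()),
            "consensus_panel": int(selected.sum()),
        },
        thresholds={
            "vip_min": vip_min, "hd_max_pct": hd_max_pct,
            "aih_min_pct": aih_min_pct, "rel_freq_min": rel_freq_min,
        },
    )


def filter_candidates(
    table: pd.DataFrame,
    vip_min: float = 1.0,
    hd_max_pct: float = 25.0,
    aih_min_pct: float = 50.0,
    vip_col: str = "vip",
    hd_col: str = "hd_pct",
    aih_col: str = "aih_pct",
) -> pd.DataFrame:
    """Apply the VIP/frequency filters to a flat candidate table (one VIP
    value per antigen, e.g. an ensemble mean or a published list)."""
    keep = (
        (table[vip_col] > vip_min)
        & (table[hd_col] < hd_max_pct)
        & (table[aih_col] > aih_min_pct)
    )
    return table.loc[keep]
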