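"""Spot-level scan tables -> normalized MFI matrix and positivity calls.

Steps, in order:

1. ``spot_signal``: per-spot signal = foreground mean / local background
   mean (spots with non-positive background are invalid).
2. ``normalize_within_array``: a monotone affine map fitted from each
   array's human-IgG dilution-curve signals to a cross-array reference
   curve (exact least-absolute-deviation line through the best point
   pair), applied to all spots; output is in normalized-MFI units.
3. ``replicate_cv_filter``: per-antigen CV% over replicate spots; antigens
   above the ceiling are dropped for that array, survivors summarized by
   the replicate mean.
4. ``compute_threshold``: positivity threshold = mean + 2 SD of the
   pooled negative-control normalized signals.
5. ``impute_invalid_signals``: invalid cells take the antigen's mean over
   valid samples of the same group.
6. ``call_positivity``: strictly-greater-than threshold calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ThresholdSpec:
    """Positivity threshold in normalized-MFI units."""

    value: float
    rule: str = "negative controls mean + 2 SD"

    def __post_init__(self):
        if not self.value > 0:
            raise ValueError("threshold must be > 0")


@dataclass
class PreprocessResult:
    mfi: pd.DataFrame          # samples x antigens, normalized MFI
    positivity: pd.DataFrame   # samples x antigens, 0/1 calls
    threshold: ThresholdSpec
    quality: pd.DataFrame      # per (array, antigen): cv_pct, kept
    cv_max: float


def spot_signal(fg: np.ndarray | float, bg: np.ndarray | float):
    """Foreground/background ratio; NaN where the background is unusable."""
    fg = np.asarray(fg, dtype=float)
    bg = np.asarray(bg, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(bg > 0, fg / bg, np.nan)
    return out if out.ndim else float(out)


def _lad_affine_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact least-absolute-deviation line with positive slope.

    An optimal LAD line interpolates two data points, so with the handful
    of points on an IgG dilution curve the fit can be found by
    enumerating pairs; deterministic, no iterative solver.
    """
    best = None
    for i, j in combinations(range(len(x)), 2):
        if x[i] == x[j]:
            continue
        a = (y[j] - y[i]) / (x[j] - x[i])
        if a <= 0:
            continue
        b = y[i] - a * x[i]
        loss = float(np.abs(a * x + b - y).sum())
        key = (loss, a, b)
        if best is None or key < best:
            best = key
    if best is None:
        raise ValueError("degenerate IgG curve: no positive-slope fit exists")
    return best[1], best[2]


def fit_igg_map(
    igg_signals: np.ndarray, reference: np.ndarray
) -> tuple[float, float]:
    """Affine map (slope, intercept) from an array's IgG signals to the
    reference curve values (level-matched)."""
    x = np.asarray(igg_signals, dtype=float)
    y = np.asarray(reference, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError(f"need >= 3 IgG curve points, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) IgG curve")
    return _lad_affine_fit(x, y)


def reference_igg_curve(scans: pd.DataFrame) -> pd.Series:
    """Cross-array median IgG signal per dilution level, in normalized-MFI
    units (nominal amounts name the levels and set the unit scale)."""
    igg = scans[scans["control_type"] == "igg"].copy()
    if igg.empty:
        raise ValueError("scans contain no IgG curve spots")
    igg["signal"] = spot_signal(igg["fg_mean"].to_numpy(), igg["bg_mean"].to_numpy())
    med = igg.groupby("nominal_igg", observed=True)["signal"].median()
    # anchor the unit scale to the nominal amounts: median array maps onto them
    return pd.Series(med.index.to_numpy(dtype=float), index=med.index)


def normalize_within_array(
    scan: pd.DataFrame, reference_curve: pd.Series
) -> pd.DataFrame:
    """Apply the array's IgG-curve affine map to all of its spots.

    ``reference_curve`` is indexed by nominal IgG amount and holds the
    reference normalized signal per level.  Returns the scan with a
    ``normalized`` column (invalid spots stay NaN).
    """
    out = scan.copy()
    sig = spot_signal(out["fg_mean"].to_numpy(), out["bg_mean"].to_numpy())
    igg_mask = (out["control_type"] == "igg").to_numpy()
    if igg_mask.sum() < 3:
        raise ValueError("array has fewer than 3 IgG curve points")
    lv = out.loc[igg_mask, "nominal_igg"].to_numpy(dtype=float)
    ref = reference_curve.reindex(lv).to_numpy(dtype=float)
    a, b = fit_igg_map(sig[igg_mask], ref)
    out["normalized"] = a * sig + b
    return out


def compute_threshold(controls: np.ndarray) -> ThresholdSpec:
    """Mean + 2 sample SD of negative-control normalized signals."""
    c = np.asarray(controls, dtype=float)
    c = c[np.isfinite(c)]
    if len(c) < 2:
        raise ValueError("need >= 2 negative-control values")
    return ThresholdSpec(value=float(c.mean() + 2.0 * c.std(ddof=1)))


def replicate_cv_filter(
    replicates: pd.DataFrame, cv_max: float = 50.0,
    value_col: str = "normalized", by: tuple[str, ...] = ("array_id", "antigen_id"),
) -> pd.DataFrame:
    """Per-group CV% = 100 * SD / mean over replicate spots.

    Returns one row per group with columns mean, cv_pct, kept.  Groups
    with non-positive mean or CV% above the ceiling are flagged dropped.
    """
    g = replicates.groupby(list(by), observed=True)[value_col]
    out = g.agg(mean="mean", sd="std", n="count").reset_index()  # std: ddof=1
    with np.errstate(divide="ignore", invalid="ignore"):
        out["cv_pct"] = 100.0 * out["sd"] / out["mean"]
    out.loc[out["mean"] <= 0, "cv_pct"] = np.inf
    out["kept"] = out["cv_pct"] <= cv_max
    return out.drop(columns="sd")


def impute_invalid_signals(
    matrix: pd.DataFrame, samples: pd.DataFrame
) -> pd.DataFrame:
    """Replace invalid (NaN) cells by the antigen's mean over valid values
    within the sample's group; antigens with no valid value in some group
    are dropped with a warning."""
    groups = samples.set_index("sample_id")["group"].reindex(matrix.index)
    if groups.isna().any():
        missing = list(matrix.index[groups.isna()])
        raise ValueError(f"samples without group labels: {missing[:5]}")
    out = matrix.copy()
    dropped: list[str] = []
    for g, block in out.groupby(groups.to_numpy()):
        means = block.mean(axis=0, skipna=True)
        dropped.extend(means.index[means.isna()])
        out.loc[block.index] = block.fillna(means)
    if dropped:
        dropped = sorted(set(dropped))
        warnings.warn(
            f"dropping {len(dropped)} antigen(s) with no valid value in a group",
            stacklevel=2,
        )
        out = out.drop(columns=dropped)
    return out


def call_positivity(matrix: pd.DataFrame, threshold: ThresholdSpec) -> pd.DataFrame:
    """Binary recognition calls: 1 iff normalized MFI strictly exceeds the
    threshold (boundary ties are negative)."""
    if not np.isfinite(matrix.to_numpy(dtype=float)).all():
        raise ValueError("matrix must be finite; impute invalid signals first")
    return (matrix > threshold.value).astype(np.int8)


def preprocess_scans(
    scans: pd.DataFrame,
    samples: pd.DataFrame,
    cv_max: float = 50.0,
    reference_curve: pd.Series | None = None,
) -> PreprocessResult:
    """Full preprocessing of a long scan table into MFI + positivity.

    The reference IgG curve defaults to the cross-array median curve of the
    input scans (anchored to nominal amounts for the unit scale).
    """
    if reference_curve is None:
        reference_curve = reference_igg_curve(scans)
    normalized = [
        normalize_within_array(scan, reference_curve)
        for _, scan in scans.groupby("array_id", observed=True, sort=False)
    ]
    norm = pd.concat(normalized, ignore_index=True)

    ctrl = norm.loc[norm["control_type"] == "negative", "normalized"].to_numpy()
    threshold = compute_threshold(ctrl)

    spots = norm[norm["control_type"] == "none"]
    quality = replicate_cv_filter(spots, cv_max=cv_max)

    kept = quality[quality["kept"]]
    sample_of_array = (
        scans[["array_id", "sample_id"]].drop_duplicates().set_index("array_id")["sample_id"]
    )
    mat = kept.pivot(index="array_id", columns="antigen_id", values="mean")
    mat.index = sample_of_array.reindex(mat.index).to_numpy()
    mat.index.name = "sample_id"
    mat.columns = mat.columns.astype(str)
    mat.columns.name = "antigen_id"
    # rows for samples whose every antigen failed QC would otherwise vanish
    mat = mat.reindex(index=samples["sample_id"],
                      columns=sorted(set(spots["antigen_id"].astype(str))))

    mfi = impute_invalid_signals(mat, samples)
    positivity = call_positivity(mfi, threshold)
    return PreprocessResult(
        mfi=mfi, positivity=positivity, threshold=threshold,
        quality=quality, cv_max=cv_max,
    )
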