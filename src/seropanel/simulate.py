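"""Synthetic serum cohorts, protein-microarray scans and DELFIA plates.

No raw data accompany the study design this package implements, so every
downstream stage is exercised on simulated inputs that carry the same
statistical structure the analysis assumes:

* cohorts with fixed group sizes and exact (rounded) female counts;
* spot-level array scans — ~1626 antigens in replicate, negative-control
  spots calibrated so that mean + 2 SD of their normalized signal sits at
  the positivity threshold, a human-IgG dilution curve per array whose
  points share the array's multiplicative scale drift, and a small set of
  "informative" antigens elevated in recognizing samples;
* DELFIA plate tables with duplicate wells and per-group reactivity rates.

Signal model: spot intensities are log-normal; an antigen recognized by a
serum adds a configurable shift on the log scale.  Array drift is a
log-normal multiplicative factor applied to every spot including the IgG
curve, which makes within-array normalization identifiable by recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri

GROUPS = ("AIH", "HD", "HCV", "HBV")
NEGATIVE_CONTROL_IDS = ("BSA", "HSA", "Hu-GST")

SCAN_COLUMNS = [
    "array_id",
    "sample_id",
    "antigen_id",
    "replicate",
    "fg_mean",
    "bg_mean",
    "control_type",
    "nominal_igg",
]


class ConfigurationError(ValueError):
    """Raised for invalid generator specifications."""


@dataclass(frozen=True)
class GroupSpec:
    label: str
    n: int
    female_fraction: float


@dataclass(frozen=True)
class CohortSpec:
    """Cohort design: group sizes, sex composition and study phase."""

    groups: tuple[GroupSpec, ...]
    phase: str = "discovery"
    seed: int = 0

    def __post_init__(self):
        for g in self.groups:
            if g.label not in GROUPS:
                raise ConfigurationError(f"unknown group label {g.label!r}")
            if g.n < 1:
                raise ConfigurationError(f"group {g.label}: n must be >= 1, got {g.n}")
            if not 0.0 <= g.female_fraction <= 1.0:
                raise ConfigurationError(
                    f"group {g.label}: female fraction must be in [0, 1]"
                )


@dataclass(frozen=True)
class InformativeAntigen:
    """A planted discriminating antigen with per-group recognition rates."""

    antigen_id: str
    probabilities: dict[str, float]  # group label -> recognition probability
    effect: float = float(np.log(10.0))  # log-scale shift when recognized

    def __post_init__(self):
        for g, p in self.probabilities.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(
                    f"{self.antigen_id}: recognition probability for {g} not in [0,1]"
                )


@dataclass(frozen=True)
class PanelSpec:
    """Array content and noise model.

    Signal units: raw spot signals are foreground/background ratios (~1-10);
    the normalization step rescales them by ``units_scale`` into
    "normalized MFI" units, in which the positivity threshold target
    (negative-control mean + 2 SD) defaults to 4000.
    """

    n_antigens: int = 1626
    informative: tuple[InformativeAntigen, ...] = ()
    n_replicates: int = 4
    negative_control_ids: tuple[str, ...] = NEGATIVE_CONTROL_IDS
    igg_levels: tuple[float, ...] = tuple(500.0 * 2.0**k for k in range(8))
    igg_replicates: int = 2
    spot_cv: float = 0.08  # log-sd of replicate spot noise
    drift_sigma: float = 0.3  # log-sd of per-array multiplicative drift
    baseline_log_mfi: float = float(np.log(1.2))  # ratio units (x1000 => MFI)
    baseline_log_sd: float = 0.45
    threshold_target: float = 4000.0  # normalized MFI units
    control_log_sd: float = 0.15
    recognition_rho: float = 0.0  # copula correlation of recognition events
    outliers: dict[str, float] = field(default_factory=dict)  # sample -> factor
    units_scale: float = 1000.0
    bg_log_mean: float = float(np.log(2000.0))
    bg_log_sd: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 2:
            raise ConfigurationError("replicate count must be >= 2")
        ids = set(self.antigen_ids())
        for inf in self.informative:
            if inf.antigen_id not in ids:
                raise ConfigurationError(
                    f"informative antigen {inf.antigen_id!r} not in panel"
                )
        if not 0.0 <= self.recognition_rho < 1.0:
            raise ConfigurationError("recognition_rho must be in [0, 1)")

    def antigen_ids(self) -> list[str]:
        width = len(str(self.n_antigens))
        return [f"AG{i:0{width}d}" for i in range(1, self.n_antigens + 1)]


def default_informative(
    n_informative: int = 20,
    n_antigens: int = 1626,
    aih_range: tuple[float, float] = (0.7, 0.9),
    hd_prob: float = 0.02,
    effect: float = float(np.log(10.0)),
    seed: int = 0,
) -> tuple[InformativeAntigen, ...]:
    """Evenly spaced planted antigens with AIH recognition in ``aih_range``.

    AIH probabilities are deterministic (linearly spaced across the range)
    so the planted design is reproducible independently of the noise seed.
    """
    width = len(str(n_antigens))
    idx = np.linspace(1, n_antigens, n_informative + 2)[1:-1].round().astype(int)
    probs = np.linspace(aih_range[0], aih_range[1], n_informative)
    rng = np.random.default_rng(seed)
    probs = rng.permutation(probs)
    return tuple(
        InformativeAntigen(
            antigen_id=f"AG{i:0{width}d}",
            probabilities={"AIH": float(p), "HD": hd_prob, "HCV": hd_prob, "HBV": hd_prob},
            effect=effect,
        )
        for i, p in zip(idx, probs)
    )


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """One record per sample: id, group, sex, phase.

    Female counts are exact per group (``round(n * female_fraction)``), not
    Bernoulli draws, so downstream sex-ratio constraints are satisfiable by
    construction; which samples are female is a seeded permutation.
    """
    rng = np.random.default_rng(spec.seed)
    tag = spec.phase[0].upper()
    rows = []
    for g in spec.groups:
        n_f = int(round(g.n * g.female_fraction))
        sexes = np.array(["F"] * n_f + ["M"] * (g.n - n_f))
        rng.shuffle(sexes)
        for i, sex in enumerate(sexes, start=1):
            rows.append(
                {
                    "sample_id": f"{g.label}-{tag}{i:03d}",
                    "group": g.label,
                    "sex": sex,
                    "phase": spec.phase,
                }
            )
    return pd.DataFrame(rows)


def _control_log_mean(target: float, sigma: float) -> float:
    # mean + 2 SD of a log-normal equals `target`:
    # m (1 + 2 sqrt(e^{s^2} - 1)) = target, mu = log m - s^2 / 2
    c = np.sqrt(np.expm1(sigma**2))
    m = target / (1.0 + 2.0 * c)
    return float(np.log(m) - sigma**2 / 2.0)


def _recognition_matrix(
    samples: pd.DataFrame, panel: PanelSpec, rng: np.random.Generator
) -> np.ndarray:
    """Bernoulli recognition events, optionally correlated across antigens.

    A Gaussian copula couples the events: each sample draws a latent
    reactivity factor shared by all informative antigens
    (``recognition_rho`` is the pairwise latent correlation), so strongly
    co-recognized antigen blocks — as seen in real seroreactivity data —
    can be emulated.
    """
    n = len(samples)
    k = len(panel.informative)
    out = np.zeros((n, k), dtype=bool)
    if k == 0:
        return out
    rho = panel.recognition_rho
    u = rng.standard_normal(n)[:, None]
    eps = rng.standard_normal((n, k))
    z = np.sqrt(rho) * u + np.sqrt(1.0 - rho) * eps
    for j, inf in enumerate(panel.informative):
        p = np.array(
            [inf.probabilities.get(g, 0.0) for g in samples["group"]], dtype=float
        )
        crit = np.where(p >= 1.0, np.inf, np.where(p <= 0.0, -np.inf, ndtri(p)))
        out[:, j] = z[:, j] < crit
    return out


def generate_array_scans(samples: pd.DataFrame, panel: PanelSpec) -> pd.DataFrame:
    """Spot-level scan table, one array per sample (long format).

    Columns: array_id, sample_id, antigen_id, replicate, fg_mean, bg_mean,
    control_type ("none"/"negative"/"igg"), nominal_igg (NaN off-curve).

    The per-array drift factor multiplies every spot, IgG curve included;
    an outlier sample's factor multiplies antigen and control spots only
    (aberrant serum reactivity does not touch the detection-antibody
    calibration curve, so normalization cannot absorb it).
    """
    rng = np.random.default_rng(panel.seed)
    antigens = panel.antigen_ids()
    n_s, n_a, n_rep = len(samples), len(antigens), panel.n_replicates

    drift = np.exp(rng.normal(0.0, panel.drift_sigma, size=n_s))
    out_factor = np.array(
        [panel.outliers.get(s, 1.0) for s in samples["sample_id"]], dtype=float
    )

    # sample x antigen true log-ratio
    logr = rng.normal(panel.baseline_log_mfi, panel.baseline_log_sd, size=(n_s, n_a))
    recog = _recognition_matrix(samples, panel, rng)
    idx = {a: i for i, a in enumerate(antigens)}
    for j, inf in enumerate(panel.informative):
        logr[:, idx[inf.antigen_id]] += inf.effect * recog[:, j]

    # replicate spot ratios with multiplicative noise, drift and outlier shift
    ratios = np.exp(
        logr[:, :, None] + rng.normal(0.0, panel.spot_cv, size=(n_s, n_a, n_rep))
    )
    ratios *= (drift * out_factor)[:, None, None]

    frames = []
    sample_ids = samples["sample_id"].to_numpy()

    ag_rep = np.repeat(antigens, n_rep)
    rep_idx = np.tile(np.arange(n_rep), n_a)
    frames.append(
        pd.DataFrame(
            {
                "array_id": np.repeat(sample_ids, n_a * n_rep),
                "sample_id": np.repeat(sample_ids, n_a * n_rep),
                "antigen_id": np.tile(ag_rep, n_s),
                "replicate": np.tile(rep_idx, n_s),
                "ratio": ratios.reshape(-1),
                "control_type": "none",
                "nominal_igg": np.nan,
            }
        )
    )

    # negative-control spots, calibrated so mean + 2 SD ~= threshold target
    mu_c = _control_log_mean(panel.threshold_target / panel.units_scale,
                             panel.control_log_sd)
    n_c = len(panel.negative_control_ids)
    c_ratio = np.exp(
        rng.normal(mu_c, panel.control_log_sd, size=(n_s, n_c, n_rep))
    ) * (drift * out_factor)[:, None, None]
    frames.append(
        pd.DataFrame(
            {
                "array_id": np.repeat(sample_ids, n_c * n_rep),
                "sample_id": np.repeat(sample_ids, n_c * n_rep),
                "antigen_id": np.tile(np.repeat(panel.negative_control_ids, n_rep), n_s),
                "replicate": np.tile(np.tile(np.arange(n_rep), n_c), n_s),
                "ratio": c_ratio.reshape(-1),
                "control_type": "negative",
                "nominal_igg": np.nan,
            }
        )
    )

    # human-IgG dilution curve: nominal values in normalized-MFI units
    levels = np.asarray(panel.igg_levels, dtype=float)
    n_l, n_ir = len(levels), panel.igg_replicates
    igg_ratio = (levels / panel.units_scale)[None, :, None] * np.exp(
        rng.normal(0.0, panel.spot_cv, size=(n_s, n_l, n_ir))
    ) * drift[:, None, None]
    frames.append(
        pd.DataFrame(
            {
                "array_id": np.repeat(sample_ids, n_l * n_ir),
                "sample_id": np.repeat(sample_ids, n_l * n_ir),
                "antigen_id": np.tile(
                    np.repeat([f"IgG-{v:g}" for v in levels], n_ir), n_s
                ),
                "replicate": np.tile(np.tile(np.arange(n_ir), n_l), n_s),
                "ratio": igg_ratio.reshape(-1),
                "control_type": "igg",
                "nominal_igg": np.tile(np.repeat(levels, n_ir), n_s),
            }
        )
    )

    scans = pd.concat(frames, ignore_index=True)
    # split the ratio into foreground/background intensities
    bg = np.exp(rng.normal(panel.bg_log_mean, panel.bg_log_sd, size=len(scans)))
    scans["bg_mean"] = bg
    scans["fg_mean"] = scans.pop("ratio") * bg
    scans["antigen_id"] = scans["antigen_id"].astype("category")
    scans["control_type"] = scans["control_type"].astype("category")
    return scans[SCAN_COLUMNS]


# ---------------------------------------------------------------------------
# DELFIA plates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DelfiaSpec:
    """Plate immunoassay noise model.

    A sample is *reactive* to a marker with the configured per-group
    probability; reactive sera read a log-normal multiple of the plate
    background.  Non-reactive sera sit at the flat plate background except
    for a sparse "sticky serum" fraction with an exponential uplift — this
    contamination structure is what makes the mean + 1 SEM positivity rule
    produce realistic high specificities (see docs/methods.md).
    """

    reactivity: dict[str, dict[str, float]] = field(default_factory=dict)
    baseline: float = 100.0
    sticky_rate: float = 0.15
    sticky_scale: float = 1.0  # mean relative uplift of sticky sera
    effect_log_mean: float = float(np.log(8.0))
    effect_log_sd: float = 0.4
    well_cv: float = 0.02  # log-sd of per-well noise
    n_wells: int = 2
    seed: int = 0


def generate_delfia_plate(
    samples: pd.DataFrame, markers: list[str], spec: DelfiaSpec
) -> pd.DataFrame:
    """Long table: sample_id, group, marker, well, fluorescence.

    Markers are coated in duplicate wells (``n_wells``); reactivity events
    are independent across markers given the per-group rates in
    ``spec.reactivity[marker]``.
    """
    if not markers:
        raise ConfigurationError("markers must be non-empty")
    known = set(samples["sample_id"])
    for m in markers:
        rates = spec.reactivity.get(m)
        if rates is None:
            raise ConfigurationError(f"no reactivity rates configured for {m!r}")
        for sid in rates.get("samples", ()):  # pragma: no cover - defensive
            if sid not in known:
                raise ConfigurationError(f"unknown sample id {sid!r}")
    rng = np.random.default_rng(spec.seed)
    rows = []
    groups = samples["group"].to_numpy()
    sids = samples["sample_id"].to_numpy()
    n = len(samples)
    sticky = rng.random((n, len(markers))) < spec.sticky_rate
    sticky_uplift = rng.exponential(spec.sticky_scale, size=(n, len(markers)))
    for j, m in enumerate(markers):
        p = np.array([spec.reactivity[m].get(g, 0.0) for g in groups])
        reactive = rng.random(n) < p
        level = np.full(n, spec.baseline)
        level[sticky[:, j]] *= 1.0 + sticky_uplift[sticky[:, j], j]
        level[reactive] *= np.exp(
            rng.normal(spec.effect_log_mean, spec.effect_log_sd, size=int(reactive.sum()))
        )
        for w in range(spec.n_wells):
            noise = np.exp(rng.normal(0.0, spec.well_cv, size=n)) if spec.well_cv > 0 else 1.0
            rows.append(
                pd.DataFrame(
                    {
                        "sample_id": sids,
                        "group": groups,
                        "marker": m,
                        "well": w,
                        "fluorescence": level * noise,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


# canonical cohort designs (discovery: 15 AIH / 78 HD; validation adds VH)
def discovery_cohort_spec(seed: int = 0) -> CohortSpec:
    return CohortSpec(
        groups=(
            GroupSpec("AIH", 15, 13 / 15),
            GroupSpec("HD", 78, 20 / 78),
        ),
        phase="discovery",
        seed=seed,
    )


def validation_cohort_spec(seed: int = 0) -> CohortSpec:
    return CohortSpec(
        groups=(
            GroupSpec("AIH", 40, 34 / 40),
            GroupSpec("HD", 35, 31 / 35),
            GroupSpec("HCV", 72, 27 / 72),
            GroupSpec("HBV", 23, 9 / 23),
        ),
        phase="validation",
        seed=seed,
    )
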