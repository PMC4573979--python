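"""End-to-end orchestration: simulate -> preprocess -> balanced ensemble
-> PLS-DA/VIP ranking -> model validation -> consensus panel (discovery),
and DELFIA positivity -> sensitivity/specificity -> ROC (validation).

A single global seed is expanded into per-stage seeds through
``numpy.random.SeedSequence`` with a fixed stage order, so every output
is reproducible byte-for-byte from the configuration alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .delfia import (
    average_duplicates,
    combine_markers,
    delfia_positivity,
    group_tests,
    roc_auc,
    sens_spec,
)
from .ensemble import EnsembleConfig, balanced_subsets, pca_outlier_screen
from .plsda import fit_plsda, rsvm_rank, top_k_features, vip_feature_set
from .preprocess import preprocess_scans
from .simulate import (
    CohortSpec,
    DelfiaSpec,
    GroupSpec,
    PanelSpec,
    default_informative,
    discovery_cohort_spec,
    generate_array_scans,
    generate_cohort,
    generate_delfia_plate,
    validation_cohort_spec,
)
from .stability import frequency_table, multicriteria_select, stability_matrix
from .validate_model import ValidationConfig, cross_validate, permutation_test

log = logging.getLogger("seropanel")

_STAGES = (
    "cohort", "panel", "informative", "ensemble", "validation",
    "permutation", "delfia_cohort", "delfia",
)


def stage_seeds(global_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds (< 2**31) from one global seed."""
    ss = np.random.SeedSequence(global_seed)
    states = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(len(_STAGES))]
    return dict(zip(_STAGES, states))


@dataclass
class FilterThresholds:
    vip_min: float = 1.0
    hd_max_pct: float = 25.0
    aih_min_pct: float = 50.0
    rel_freq_min: float = 1.0


@dataclass
class PanelDesign:
    """Synthetic-array design knobs surfaced in the run configuration."""

    n_antigens: int = 1626
    n_informative: int = 20
    aih_range: tuple[float, float] = (0.7, 0.9)
    hd_prob: float = 0.02
    effect: float = float(np.log(10.0))
    recognition_rho: float = 0.0
    outliers: dict[str, float] = field(default_factory=dict)


@dataclass
class RunConfig:
    seed: int = 0
    panel: PanelDesign = field(default_factory=PanelDesign)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    validation: ValidationConfig = field(default_factory=ValidationConfig)
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    cv_max: float = 50.0
    include_rsvm: bool = True
    run_permutation: bool = True
    markers: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "UNQ9419": {"AIH": 0.45, "HD": 0.0, "HCV": 0.02, "HBV": 0.02},
            "CHAD": {"AIH": 0.53, "HD": 0.06, "HCV": 0.05, "HBV": 0.05},
        }
    )
    combination_modes: tuple[str, ...] = ("or-rule", "score-sum")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "panel" in kwargs:
            p = dict(kwargs["panel"])
            if "aih_range" in p:
                p["aih_range"] = tuple(p["aih_range"])
            kwargs["panel"] = PanelDesign(**p)
        if "ensemble" in kwargs:
            kwargs["ensemble"] = EnsembleConfig(**kwargs["ensemble"])
        if "validation" in kwargs:
            kwargs["validation"] = ValidationConfig(**kwargs["validation"])
        if "thresholds" in kwargs:
            kwargs["thresholds"] = FilterThresholds(**kwargs["thresholds"])
        if "combination_modes" in kwargs:
            kwargs["combination_modes"] = tuple(kwargs["combination_modes"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return json.loads(json.dumps(asdict(self), default=list))


def build_panel_spec(cfg: RunConfig, seeds: dict[str, int]) -> PanelSpec:
    informative = default_informative(
        n_informative=cfg.panel.n_informative,
        n_antigens=cfg.panel.n_antigens,
        aih_range=cfg.panel.aih_range,
        hd_prob=cfg.panel.hd_prob,
        effect=cfg.panel.effect,
        seed=seeds["informative"],
    )
    return PanelSpec(
        n_antigens=cfg.panel.n_antigens,
        informative=informative,
        recognition_rho=cfg.panel.recognition_rho,
        outliers=dict(cfg.panel.outliers),
        seed=seeds["panel"],
    )


@dataclass
class DiscoveryReport:
    samples: pd.DataFrame
    excluded: list[str]
    planted: list[str]
    vip_by_subset: pd.DataFrame
    panel: object                       # stability.PanelSelection
    stability: dict                     # ranker -> StabilityResult
    validation_summary: pd.DataFrame    # subset_id, A, R2Y, Q2Y
    permutation: object | None
    threshold: float
    manifest: dict


def run_discovery(
    cfg: RunConfig,
    outdir: str | Path | None = None,
    cohort: CohortSpec | None = None,
) -> DiscoveryReport:
    seeds = stage_seeds(cfg.seed)
    t0 = time.perf_counter()
    cohort = cohort or discovery_cohort_spec(seed=seeds["cohort"])
    samples = generate_cohort(cohort)
    panel_spec = build_panel_spec(cfg, seeds)
    planted = [inf.antigen_id for inf in panel_spec.informative]
    scans = generate_array_scans(samples, panel_spec)
    log.info("simulate: %d samples, %d spot records (%.1fs)",
             len(samples), len(scans), time.perf_counter() - t0)

    pre = preprocess_scans(scans, samples, cv_max=cfg.cv_max)
    log.info("preprocess: threshold %.0f, %d antigens retained",
             pre.threshold.value, pre.mfi.shape[1])

    screen = pca_outlier_screen(pre.mfi)
    excluded = list(screen.flags.index[screen.flags])
    kept = samples[~samples["sample_id"].isin(excluded)].reset_index(drop=True)
    mfi = pre.mfi.drop(index=excluded)
    positivity = pre.positivity.drop(index=excluded)
    if excluded:
        log.info("outlier screen: excluded %s", excluded)

    ens = balanced_subsets(kept, cfg.ensemble)
    labels = kept.set_index("sample_id")["group"]

    vip_cols, rows, pls_sets, rsvm_sets = {}, [], [], []
    first_subset = None
    for i, subset in enumerate(ens.subsets):
        X = mfi.loc[subset]
        y = labels.loc[subset].to_numpy()
        vcfg = ValidationConfig(
            k_folds=cfg.validation.k_folds,
            max_components=cfg.validation.max_components,
            n_permutations=cfg.validation.n_permutations,
            seed=(seeds["validation"] + i) % 2**31,
        )
        cv = cross_validate(X, y, vcfg, positive_label=cfg.ensemble.minority_group)
        model = fit_plsda(X, y, cv.chosen_a,
                          positive_label=cfg.ensemble.minority_group)
        vip = model.vip
        vip_cols[f"subset{i:02d}"] = vip
        rows.append({"subset_id": f"subset{i:02d}", "A": cv.chosen_a,
                     "R2Y": cv.r2y, "Q2Y": cv.q2y})
        fset = vip_feature_set(vip, cfg.thresholds.vip_min)
        pls_sets.append(fset)
        if cfg.include_rsvm:
            ranked = rsvm_rank(X, y, positive_label=cfg.ensemble.minority_group)
            rsvm_sets.append(top_k_features(ranked, len(fset)))
        if first_subset is None:
            first_subset = (X, y, cv.chosen_a)
    vip_by_subset = pd.DataFrame(vip_cols)
    validation_summary = pd.DataFrame(rows)
    log.info("ranking: %d subsets fitted, median Q2Y %.3f",
             len(ens.subsets), validation_summary["Q2Y"].median())

    stab = {"PLS-DA": stability_matrix(pls_sets, "PLS-DA")}
    if cfg.include_rsvm:
        stab["R-SVM"] = stability_matrix(rsvm_sets, "R-SVM")

    freq = frequency_table(positivity, kept)
    panel = multicriteria_select(
        vip_by_subset, freq,
        vip_min=cfg.thresholds.vip_min,
        hd_max_pct=cfg.thresholds.hd_max_pct,
        aih_min_pct=cfg.thresholds.aih_min_pct,
        rel_freq_min=cfg.thresholds.rel_freq_min,
    )
    log.info("selection: funnel %s", panel.stage_counts)

    perm = None
    if cfg.run_permutation and first_subset is not None:
        X, y, a = first_subset
        pcfg = ValidationConfig(
            k_folds=cfg.validation.k_folds, max_components=a,
            n_permutations=cfg.validation.n_permutations,
            seed=seeds["permutation"],
        )
        perm = permutation_test(X, y, pcfg, n_components=a,
                                positive_label=cfg.ensemble.minority_group)
        log.info("permutation: observed Q2Y %.3f, p = %.4g",
                 perm.observed_q2y, perm.p_q2y)

    manifest = {
        "tool": {"name": "seropanel", "version": __version__},
        "config": cfg.to_dict(),
        "stage_seeds": seeds,
        "n_samples": int(len(samples)),
        "excluded_outliers": excluded,
        "threshold": float(pre.threshold.value),
        "stage_counts": panel.stage_counts,
        "stability_average": {k: v.average for k, v in stab.items()},
        "panel": list(panel.antigens),
        "outputs": {},
    }
    report = DiscoveryReport(
        samples=samples, excluded=excluded, planted=planted,
        vip_by_subset=vip_by_subset, panel=panel, stability=stab,
        validation_summary=validation_summary, permutation=perm,
        threshold=float(pre.threshold.value), manifest=manifest,
    )
    if outdir is not None:
        _write_discovery(report, ens, Path(outdir))
    return report


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def _write_discovery(report: DiscoveryReport, ens, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    panel_tbl = report.panel.table.copy()
    _write_tsv(panel_tbl, outdir / "panel.tsv")
    _write_tsv(report.validation_summary, outdir / "validation_summary.tsv",
               index=False)
    _write_tsv(report.vip_by_subset, outdir / "vip_by_subset.tsv")
    for name, res in report.stability.items():
        tag = name.lower().replace("-", "")
        _write_tsv(res.matrix, outdir / f"stability_{tag}.tsv")
    (outdir / "ensemble.json").write_text(json.dumps(
        {f"subset{i:02d}": ids for i, ids in enumerate(ens.subsets)},
        indent=1, sort_keys=True))
    (outdir / "venn_counts.json").write_text(
        json.dumps(report.panel.stage_counts, indent=1, sort_keys=True))
    outputs = {}
    for f in sorted(outdir.iterdir()):
        if f.name != "manifest.json":
            outputs[f.name] = _sha256(f)
    report.manifest["outputs"] = outputs
    (outdir / "manifest.json").write_text(
        json.dumps(report.manifest, indent=1, sort_keys=True))


@dataclass
class ValidationReport:
    samples: pd.DataFrame
    performance: pd.DataFrame
    roc: dict                  # name -> ROCResult
    tests: dict                # marker -> group_tests dict
    thresholds: dict           # marker -> DelfiaThreshold


def run_validation(
    cfg: RunConfig,
    outdir: str | Path | None = None,
    cohort: CohortSpec | None = None,
) -> ValidationReport:
    if not cfg.markers:
        raise ValueError("marker list is empty")
    seeds = stage_seeds(cfg.seed)
    cohort = cohort or validation_cohort_spec(seed=seeds["delfia_cohort"])
    samples = generate_cohort(cohort)
    groups = samples.set_index("sample_id")["group"]
    if not (groups == "HD").any() or not (groups == "AIH").any():
        raise ValueError("validation cohort must contain AIH and HD samples")

    markers = list(cfg.markers)
    spec = DelfiaSpec(reactivity=cfg.markers, seed=seeds["delfia"])
    plate = generate_delfia_plate(samples, markers, spec)
    data = average_duplicates(plate)
    groups = groups.reindex(data.index)
    hd_mask = groups == "HD"
    vh_mask = groups.isin(["HCV", "HBV"])
    no_aih = groups != "AIH"

    calls, thresholds = {}, {}
    for m in markers:
        c, thr = delfia_positivity(data[m], data.loc[hd_mask, m].to_numpy(), m)
        calls[m], thresholds[m] = c, thr
    calls = pd.DataFrame(calls)

    perf_rows, roc_results, tests = [], {}, {}
    vh_labels = groups.where(~vh_mask, "VH")

    def perf(name: str, call_vec: pd.Series) -> dict:
        se, sp_hd = sens_spec(call_vec, groups, "AIH", "HD")
        _, sp_vh = sens_spec(call_vec, vh_labels, "AIH", "VH")
        return {"marker": name, "SE_pct": se, "SP_HD_pct": sp_hd,
                "SP_VH_pct": sp_vh}

    for m in markers:
        row = perf(m, calls[m])
        tests[m] = group_tests(data[m], calls[m], groups, ("AIH", "HD"))
        row["p_calls"] = tests[m]["p_calls"]
        row["p_intensity"] = tests[m]["p_intensity"]
        perf_rows.append(row)
        roc_results[m] = roc_auc(
            data[m], (groups == "AIH").astype(int), positive=1,
            control_definition="no AIH (HD + HCV + HBV)",
        )

    if len(markers) >= 2:
        combo_name = "+".join(markers)
        if "or-rule" in cfg.combination_modes:
            combo_calls = combine_markers(data, markers, "or-rule", calls=calls)
            perf_rows.append(perf(f"{combo_name} (or-rule)", combo_calls))
        if "score-sum" in cfg.combination_modes:
            score = combine_markers(data, markers, "score-sum", hd_mask=hd_mask)
            roc_results[f"{combo_name} (score-sum)"] = roc_auc(
                score, (groups == "AIH").astype(int), positive=1,
                control_definition="no AIH (HD + HCV + HBV)",
            )
    performance = pd.DataFrame(perf_rows)
    report = ValidationReport(
        samples=samples, performance=performance, roc=roc_results,
        tests=tests, thresholds=thresholds,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_tsv(performance, outdir / "performance.tsv", index=False)
        for name, r in roc_results.items():
            tag = name.replace("+", "_").replace(" ", "").replace("(", "_").replace(")", "")
            _write_tsv(r.curve, outdir / f"roc_{tag}.tsv", index=False)
        (outdir / "roc_summary.json").write_text(json.dumps(
            {name: {"auc": r.auc, "best_se": r.best_se, "best_sp": r.best_sp}
             for name, r in roc_results.items()}, indent=1, sort_keys=True))
    return report


def run_all(cfg: RunConfig, outdir: str | Path) -> tuple[DiscoveryReport, ValidationReport]:
    outdir = Path(outdir)
    disc = run_discovery(cfg, outdir / "discovery")
    val = run_validation(cfg, outdir / "validation")
    return disc, val
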