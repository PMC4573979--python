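"""Validation-phase analytics on a synthetic DELFIA screen: positivity
against the HD mean + 1 SEM rule, sensitivity/specificity versus HD and
viral-hepatitis controls, group tests, ROC/AUC against the pooled
"no AIH" class, and the two marker-combination modes.
"""

from pathlib import Path

from seropanel.pipeline import RunConfig, run_validation

SEED = 1
RESULTS = Path(__file__).resolve().parents[1] / "results" / "validation"


def main() -> None:
    report = run_validation(RunConfig(seed=SEED), outdir=RESULTS)
    perf = report.performance.copy()
    for c in ("SE_pct", "SP_HD_pct", "SP_VH_pct"):
        perf[c] = perf[c].round(1)
    print("validation cohort:",
          report.samples["group"].value_counts().to_dict())
    print(perf.to_string(index=False))
    for marker, thr in report.thresholds.items():
        t = report.tests[marker]
        print(f"{marker}: threshold {thr.value:.1f} "
              f"(HD mean {thr.hd_mean:.1f} + SEM {thr.hd_sem:.1f}); "
              f"calls p = {t['p_calls']:.2e}{t['stars_calls']}, "
              f"intensity p = {t['p_intensity']:.2e}{t['stars_intensity']}")
    for name, roc in report.roc.items():
        print(f"ROC {name}: AUC {roc.auc:.3f}, best cut-off {roc.best_cutoff:.1f} "
              f"(SE {roc.best_se:.1f}%, SP {roc.best_sp:.1f}%) "
              f"vs {roc.control_definition}")


if __name__ == "__main__":
    main()
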