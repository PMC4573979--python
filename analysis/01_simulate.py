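"""Generate the synthetic discovery cohort and its protein-microarray
scans, and summarize what was planted.

Writes the sample table and a small design summary under results/;
the full spot-level scan table (~600k rows) goes to scratch/.
"""

import json
from pathlib import Path

from seropanel.pipeline import RunConfig, build_panel_spec, stage_seeds
from seropanel.simulate import (
    discovery_cohort_spec,
    generate_array_scans,
    generate_cohort,
)

SEED = 1
RESULTS = Path(__file__).resolve().parents[1] / "results" / "simulated"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "simulated"


def main() -> None:
    cfg = RunConfig(seed=SEED)
    seeds = stage_seeds(cfg.seed)
    samples = generate_cohort(discovery_cohort_spec(seed=seeds["cohort"]))
    panel = build_panel_spec(cfg, seeds)
    scans = generate_array_scans(samples, panel)

    RESULTS.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    samples.to_csv(RESULTS / "samples.tsv", sep="\t", index=False)
    scans.to_csv(SCRATCH / "scans.tsv", sep="\t", index=False, float_format="%.6g")

    design = {
        "n_samples": int(len(samples)),
        "groups": samples["group"].value_counts().to_dict(),
        "n_antigens": panel.n_antigens,
        "n_replicates": panel.n_replicates,
        "planted_antigens": {
            inf.antigen_id: inf.probabilities["AIH"] for inf in panel.informative
        },
        "spot_records": int(len(scans)),
    }
    (RESULTS / "design.json").write_text(json.dumps(design, indent=1, sort_keys=True))
    print(
        f"simulated {design['n_samples']} arrays "
        f"({design['groups']}) x {panel.n_antigens} antigens in quadruplicate: "
        f"{design['spot_records']} spot records"
    )
    print(f"planted {len(panel.informative)} informative antigens "
          f"(AIH recognition {min(design['planted_antigens'].values()):.2f}"
          f"-{max(design['planted_antigens'].values()):.2f})")
    print(f"tables -> {RESULTS}, full scans -> {SCRATCH}")


if __name__ == "__main__":
    main()
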