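"""Build the AMI analysis cohort: exclusion cascade, first-admission
selection, rare-code filtering, and the hospital-stratified 80/10/10 split.

Writes the exclusion flow (JSON, mirroring a cohort flow diagram) and a
cohort summary under results/.
"""

import json
import pathlib
import sys

from readmit.cohort import ConditionConfig, build_cohort
from readmit.synthetic_claims import default_config, generate_dataset

OUT = pathlib.Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = default_config("ami", seed=seed)
    _, universe, raw = generate_dataset(cfg)
    condition = ConditionConfig.from_universe(universe, "ami")
    coh = build_cohort(raw, condition, min_code_count=10, seed=seed)

    with open(OUT / "02_exclusion_log.json", "w") as fh:
        fh.write(coh.exclusion_log.to_json())

    split_counts = {part: int((coh.split == part).sum())
                    for part in ("train", "validation", "test")}
    summary = {
        "seed": seed,
        "n_raw": int(len(raw)),
        "n_after_inclusion": coh.exclusion_log.n_input,
        "n_after_exclusions": coh.exclusion_log.n_final,
        "n_cohort": int(len(coh.records)),
        "n_hospitals": int(coh.records["hospital_id"].nunique()),
        "dx_vocabulary": len(coh.dx_vocabulary),
        "proc_vocabulary": len(coh.proc_vocabulary),
        "split": split_counts,
        "unplanned_readmission_rate": float(coh.y.mean()),
    }
    with open(OUT / "02_cohort_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)

    print("Exclusion cascade (removals against survivors of previous rule):")
    for rule, n in coh.exclusion_log.steps:
        print(f"  {rule:>15}: -{n}")
    print(f"Cohort: {summary['n_cohort']} records "
          f"({summary['n_after_inclusion']} entered, first admission per "
          f"patient kept) across {summary['n_hospitals']} hospitals.")
    print(f"Vocabulary after the >=10-occurrence filter: "
          f"{summary['dx_vocabulary']} diagnosis / "
          f"{summary['proc_vocabulary']} procedure codes.")
    print(f"Split sizes: {split_counts}; unplanned readmission rate "
          f"{summary['unplanned_readmission_rate']:.3f}.")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
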