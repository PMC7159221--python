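"""Elderly-subset sensitivity analysis: repeat the model comparison on
patients aged 65 and over.

Restricting by age removes one of the strongest predictors, so overall
discrimination is expected to drop while the relative ordering of the
models is unchanged. Run after (or independently of) 04.
"""

import pathlib
import sys

from readmit.evaluation import ExperimentConfig, run_experiment, save_report
from readmit.synthetic_claims import default_config

OUT = pathlib.Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = ExperimentConfig(generator=default_config("ami"), seed=seed,
                           elderly_only=True)
    report = run_experiment(cfg)
    save_report(report, OUT / "06_report_elderly.json",
                OUT / "06_report_elderly.md")
    print(f"Elderly-only cohort: {report['config']['n_cohort_records']} "
          "records (age >= 65).")
    print("Test AUC by model (elderly subset):")
    for m, a in report["auc"].items():
        print(f"  {m:>5}: {a:.3f}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
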