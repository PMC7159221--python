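"""Generate the synthetic AMI-like claims table and summarize its structure.

Writes the claims table (CSV + parquet, ground truth in sidecars) under
results/claims/ and a JSON summary of the calibration-relevant statistics:
unadjusted readmission rate, demographic and code-count moments, and the
skew of the code prevalence distribution.
"""

import json
import pathlib
import sys

import numpy as np

from readmit.synthetic_claims import (default_config, generate_dataset,
                                      incidence_matrix, write_claims)

OUT = pathlib.Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 0) -> None:
    out = OUT / "claims"
    out.mkdir(parents=True, exist_ok=True)
    cfg = default_config("ami", seed=seed)
    hospitals, universe, table = generate_dataset(cfg)

    write_claims(table, out / "ami_claims.csv", fmt="csv")
    write_claims(table, out / "ami_claims.parquet", fmt="parquet")
    hospitals.to_csv(out / "hospitals.csv", index=False)

    sec_lens = np.array([len(s) for s in table["secondary_dx"]])
    proc_lens = np.array([len(p) for p in table["procedures"]])
    M = incidence_matrix(table, universe.dx_codes, include_principal=False,
                         include_procedures=False)
    emp = np.asarray(M.mean(axis=0)).ravel()
    summary = {
        "seed": seed,
        "n_hospitals": int(len(hospitals)),
        "n_admissions": int(len(table)),
        "unadjusted_readmission_rate": float(table["readmit_30d"].mean()),
        "age_mean": float(table["age"].mean()),
        "age_sd": float(table["age"].std()),
        "female_frac": float(table["female"].mean()),
        "secondary_dx_mean": float(sec_lens.mean()),
        "secondary_dx_sd": float(sec_lens.std()),
        "proc_mean": float(proc_lens.mean()),
        "proc_sd": float(proc_lens.std()),
        "top_code_universe_prevalence": float(universe.dx_prevalence[0]),
        "top_code_empirical_frequency": float(emp.max()),
        "frac_dx_codes_below_0.02pct": float(np.mean(emp < 2e-4)),
    }
    with open(OUT / "01_claims_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print("Generated", summary["n_admissions"], "admissions across",
          summary["n_hospitals"], "hospitals.")
    print(f"Unadjusted 30-day readmission rate: "
          f"{summary['unadjusted_readmission_rate']:.3f} (calibration "
          f"target 0.120).")
    print(f"Secondary-dx count mean (SD): {summary['secondary_dx_mean']:.2f} "
          f"({summary['secondary_dx_sd']:.2f}); target 12.4 (6.1).")
    print(f"Most frequent diagnosis code: universe prevalence "
          f"{summary['top_code_universe_prevalence']:.2f}, empirical "
          f"record frequency {summary['top_code_empirical_frequency']:.2f}.")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
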