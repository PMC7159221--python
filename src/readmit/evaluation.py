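"""Discrimination metrics, cross-validated CIs, and the experiment runner.

``compute_auc`` is the Mann-Whitney AUC (tied scores get half credit —
relevant because dummy-feature models produce ties).  ``cv_auc_ci``
refits a model on k hospital-stratified folds and reports
mean +/- 1.96 * SD / sqrt(k).  ``run_experiment`` drives the whole
pipeline — generate, build cohort, embed, train the four models,
evaluate, standardize, reclassify — from one seeded config and returns a
serializable report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import rankdata

from . import standardize as std_mod
from .cohort import (Cohort, ConditionConfig, build_cohort, map_comorbidities,
                     synthetic_comorbidity_map)
from .embedding import GloveParams, count_cooccurrences, fit_glove
from .models import encode_cohort, fit_deepset, fit_ffnn, fit_gbt, fit_hlr
from .synthetic_claims import GeneratorConfig, generate_dataset, incidence_matrix

__all__ = [
    "compute_auc", "AUCResult", "cv_auc_ci",
    "ExperimentConfig", "run_experiment",
    "hlr_design", "dummy_design",
]

logger = logging.getLogger(__name__)


class MetricError(ValueError):
    pass


def compute_auc(labels, scores) -> float:
    """Mann-Whitney AUC: (concordant + 0.5 * tied) / (n_pos * n_neg)."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise MetricError("AUC undefined: labels contain a single class")
    ranks = rankdata(s)  # average ranks handle ties -> half credit
    rank_sum = ranks[y == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class AUCResult:
    auc: float
    ci_low: float
    ci_high: float
    n_folds: int
    fold_aucs: list[float] = field(default_factory=list)

    def as_dict(self) -> dict:
        return asdict(self)


def hospital_stratified_folds(hospital_ids, k: int, seed: int) -> list[np.ndarray]:
    """Deal each hospital's (shuffled) records round-robin into k folds."""
    rng = np.random.default_rng(seed)
    hosp = np.asarray(hospital_ids)
    folds: list[list[int]] = [[] for _ in range(k)]
    for h in np.unique(hosp):
        idx = rng.permutation(np.flatnonzero(hosp == h))
        offset = int(rng.integers(k))
        for j, i in enumerate(idx):
            folds[(j + offset) % k].append(int(i))
    return [np.sort(np.array(f, dtype=np.int64)) for f in folds]


def cv_auc_ci(fit_predict, hospital_ids, labels, k: int = 10,
              seed: int = 0) -> AUCResult:
    """k-fold cross-validated AUC with a normal-theory 95% CI.

    ``fit_predict(train_idx, test_idx) -> scores`` refits the model on the
    training indices and scores the held-out fold. Folds whose held-out
    labels are single-class are skipped with a warning (k reduced in the
    result). CI = mean +/- 1.96 * SD(fold AUCs) / sqrt(k_used).
    """
    y = np.asarray(labels)
    folds = hospital_stratified_folds(hospital_ids, k, seed)
    aucs = []
    for f, test_idx in enumerate(folds):
        if len(np.unique(y[test_idx])) < 2:
            logger.warning("fold %d held-out labels single-class; skipped", f)
            continue
        train_idx = np.setdiff1d(np.arange(y.size), test_idx)
        scores = fit_predict(train_idx, test_idx)
        aucs.append(compute_auc(y[test_idx], scores))
    if not aucs:
        raise MetricError("no usable folds")
    arr = np.array(aucs)
    k_used = arr.size
    half = 1.96 * arr.std(ddof=1) / np.sqrt(k_used) if k_used > 1 else 0.0
    return AUCResult(float(arr.mean()), float(arr.mean() - half),
                     float(arr.mean() + half), k_used, [float(a) for a in arr])


# ---------------------------------------------------------------------------
# feature construction shared by models


def hlr_design(records: pd.DataFrame, cmap, age_mean: float, age_sd: float,
               include_principal: bool = False):
    """Fixed-effect design for the hierarchical model: 29 comorbidity
    flags + z-scored age + sex (intercept added by the fitter)."""
    C = map_comorbidities(records, cmap, include_principal=include_principal)
    age_z = (records["age"].to_numpy(dtype=float) - age_mean) / age_sd
    female = records["female"].to_numpy(dtype=float)
    X = np.hstack([C.astype(float), age_z[:, None], female[:, None]])
    names = [f"comorb_{k:02d}" for k in range(C.shape[1])] + ["age_z", "female"]
    return X, names


def dummy_design(records: pd.DataFrame, dx_vocab: list[str],
                 proc_vocab: list[str], age_mean: float, age_sd: float):
    """Sparse design for GBT/FFNN: binary indicators for every
    in-vocabulary code (principal + secondary + procedures) plus z-scored
    age and sex."""
    codes = list(dx_vocab) + list(proc_vocab)
    M = incidence_matrix(records, codes).astype(np.float64)
    age_z = (records["age"].to_numpy(dtype=float) - age_mean) / age_sd
    female = records["female"].to_numpy(dtype=float)
    extra = sparse.csr_matrix(np.column_stack([age_z, female]))
    return sparse.hstack([M, extra], format="csr")


# ---------------------------------------------------------------------------
# experiment runner


@dataclass
class ExperimentConfig:
    """One end-to-end run: generator settings plus model/embedding scale.

    Defaults are desk-scale: ~50k admissions over 300 hospitals with a
    2,000-code diagnosis vocabulary, 50-d diagnosis and 16-d procedure
    embeddings, and reduced network widths. The published-scale settings
    (200-/50-d embeddings, 1024/256 hidden units) are reachable through
    this config.
    """

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    condition: str = "ami"
    min_code_count: int = 10
    dim_dx: int = 50
    dim_proc: int = 16
    glove_epochs: int = 12
    glove_lr: float = 0.05
    ffnn_hidden: tuple[int, int] = (256, 64)
    nn_max_epochs: int = 50
    nn_patience: int = 5
    nn_batch: int = 256
    nn_lr: float = 0.0002
    gbt_rounds: int = 8000
    gbt_depth: int = 6
    gbt_lr: float = 0.0002
    deepset_width: int = 64
    margin_scope: str = "cohort"   # "cohort" (everyone) or "test"
    standardize: bool = True       # compute rsrr + reclassification
    elderly_only: bool = False     # age >= 65 sensitivity analysis
    models: tuple[str, ...] = ("hlr", "gbt", "ffnn", "meds")
    seed: int = 0

    def spawn_seed(self, stage: int) -> int:
        return int(np.random.SeedSequence(self.seed, spawn_key=(stage,))
                   .generate_state(1)[0] % (2 ** 31 - 1))


def run_experiment(config: ExperimentConfig) -> dict:
    """Generate -> cohort -> embed -> train x4 -> evaluate -> standardize.

    Returns a JSON-serializable report: per-model test AUC, the
    rsrr tables' summaries, the HLR-vs-ME-DS reclassification
    cross-tabulation, stage timings, and the full config.
    """
    t0 = time.time()
    gen = config.generator.with_(seed=config.spawn_seed(0))
    hospitals, universe, raw = generate_dataset(gen)
    prof = gen.profile

    condition = ConditionConfig.from_universe(universe, config.condition)
    coh = build_cohort(raw, condition, min_code_count=config.min_code_count,
                       seed=config.spawn_seed(1))
    records = coh.records
    if config.elderly_only:
        keep = records["age"].to_numpy() >= 65
        records = records[keep].reset_index(drop=True)
        coh = Cohort(coh.condition, records, coh.dx_vocabulary,
                     coh.proc_vocabulary, coh.split[keep], coh.exclusion_log)
    y = coh.y
    tr, va, te = (coh.indices("train"), coh.indices("validation"),
                  coh.indices("test"))
    timings = {"generate_and_cohort": time.time() - t0}

    # --- embeddings (train+validation records only) ---------------------
    t1 = time.time()
    trval = records.iloc[np.concatenate([tr, va])]
    joint = count_cooccurrences(trval, coh.dx_vocabulary + coh.proc_vocabulary)
    dx_cm = joint.subblock(coh.dx_vocabulary)
    proc_cm = joint.subblock(coh.proc_vocabulary)
    dx_table = fit_glove(dx_cm, GloveParams(config.dim_dx,
                                            learning_rate=config.glove_lr,
                                            n_epochs=config.glove_epochs,
                                            seed=config.spawn_seed(2)))
    proc_table = fit_glove(proc_cm, GloveParams(config.dim_proc,
                                                learning_rate=config.glove_lr,
                                                n_epochs=config.glove_epochs,
                                                seed=config.spawn_seed(3)))
    timings["embedding"] = time.time() - t1

    hosp = records["hospital_id"].to_numpy()
    report: dict = {
        "config": {
            "condition": config.condition,
            "seed": config.seed,
            "n_hospitals_generated": int(len(hospitals)),
            "n_raw_admissions": int(len(raw)),
            "n_cohort_records": int(len(records)),
            "n_hospitals_cohort": int(np.unique(hosp).size),
            "dx_vocabulary": len(coh.dx_vocabulary),
            "proc_vocabulary": len(coh.proc_vocabulary),
            "unadjusted_readmission_rate": float(y.mean()),
            "elderly_only": config.elderly_only,
        },
        "exclusion_log": {r: n for r, n in coh.exclusion_log.steps},
        "auc": {},
        "timings": timings,
    }

    models: dict[str, object] = {}

    # --- HLR -------------------------------------------------------------
    if "hlr" in config.models:
        t = time.time()
        cmap = synthetic_comorbidity_map(universe)
        X_hlr, names = hlr_design(records, cmap, prof.age_mean, prof.age_sd)
        hlr = fit_hlr(X_hlr[tr], hosp[tr], y[tr], feature_names=names)
        models["hlr"] = (hlr, X_hlr)
        report["auc"]["hlr"] = compute_auc(
            y[te], hlr.predict((X_hlr[te], hosp[te])))
        report["hlr_sigma_u"] = hlr.sigma_u
        timings["hlr"] = time.time() - t

    # --- dummy-coded models ---------------------------------------------
    if {"gbt", "ffnn"} & set(config.models):
        X_dum = dummy_design(records, coh.dx_vocabulary, coh.proc_vocabulary,
                             prof.age_mean, prof.age_sd)
    if "gbt" in config.models:
        t = time.time()
        gbt = fit_gbt(X_dum[tr], y[tr], X_dum[va], y[va],
                      learning_rate=config.gbt_lr, n_rounds=config.gbt_rounds,
                      max_depth=config.gbt_depth, seed=config.spawn_seed(4))
        models["gbt"] = (gbt, X_dum)
        report["auc"]["gbt"] = compute_auc(y[te], gbt.predict(X_dum[te]))
        report["gbt_rounds_used"] = gbt.best_iteration + 1
        timings["gbt"] = time.time() - t
    if "ffnn" in config.models:
        t = time.time()
        ffnn = fit_ffnn(X_dum[tr], y[tr], X_dum[va], y[va],
                        hidden=config.ffnn_hidden, learning_rate=config.nn_lr,
                        batch_size=config.nn_batch,
                        max_epochs=config.nn_max_epochs,
                        patience=config.nn_patience, seed=config.spawn_seed(5))
        models["ffnn"] = (ffnn, X_dum)
        report["auc"]["ffnn"] = compute_auc(y[te], ffnn.predict(X_dum[te]))
        timings["ffnn"] = time.time() - t

    # --- deep set --------------------------------------------------------
    if "meds" in config.models:
        t = time.time()
        enc = encode_cohort(records, dx_table, proc_table,
                            prof.age_mean, prof.age_sd)
        meds = fit_deepset(enc.take(tr), y[tr], enc.take(va), y[va],
                           dx_table, proc_table,
                           phi_width=config.deepset_width,
                           rho_width=config.deepset_width,
                           head_width=config.deepset_width,
                           learning_rate=config.nn_lr,
                           batch_size=config.nn_batch,
                           max_epochs=config.nn_max_epochs,
                           patience=config.nn_patience,
                           seed=config.spawn_seed(6))
        models["meds"] = (meds, enc)
        report["auc"]["meds"] = compute_auc(y[te], meds.predict(enc.take(te)))
        timings["meds"] = time.time() - t

    # --- risk standardization and reclassification ----------------------
    if config.standardize and {"hlr", "meds"} <= set(models.keys()):
        t = time.time()
        scope = np.arange(len(records)) if config.margin_scope == "cohort" else te
        hlr, X_hlr = models["hlr"]
        meds, enc = models["meds"]
        rsrr_hlr = std_mod.predictive_margin_rsrr(
            hlr, (X_hlr[scope], hosp[scope]))
        rsrr_meds = std_mod.predictive_margin_rsrr(meds, enc.take(scope))
        g_hlr = std_mod.assign_groups(rsrr_hlr)
        g_meds = std_mod.assign_groups(rsrr_meds)
        xt = std_mod.cross_tabulate(g_hlr, g_meds)
        report["rsrr"] = {
            "hlr_mean": float(rsrr_hlr.rsrr.mean()),
            "meds_mean": float(rsrr_meds.rsrr.mean()),
            "n_hospitals": int(len(rsrr_hlr.hospital_ids)),
            "cross_tabulation": xt.counts.tolist(),
            "reclassification": std_mod.reclassification_summary(xt),
        }
        ratio = std_mod.ratio_rsrr(hlr, (X_hlr, hosp), hosp, y)
        common = np.isin(rsrr_hlr.hospital_ids, ratio.hospital_ids)
        order = {h: r for h, r in zip(ratio.hospital_ids, ratio.rsrr)}
        margin_vals = rsrr_hlr.rsrr[common]
        ratio_vals = np.array([order[h] for h in rsrr_hlr.hospital_ids[common]])
        from scipy.stats import spearmanr
        report["rsrr"]["margin_vs_ratio_spearman"] = float(
            spearmanr(margin_vals, ratio_vals).statistic)
        timings["standardize"] = time.time() - t

    timings["total"] = time.time() - t0
    return report


def save_report(report: dict, json_path, md_path=None) -> None:
    """Serialize a report as JSON (machine) and Markdown (human)."""
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    if md_path is None:
        return
    lines = ["# Experiment report", ""]
    cfg = report.get("config", {})
    lines.append(f"Condition: {cfg.get('condition')}, seed {cfg.get('seed')}, "
                 f"{cfg.get('n_cohort_records')} cohort records in "
                 f"{cfg.get('n_hospitals_cohort')} hospitals; unadjusted "
                 f"readmission rate "
                 f"{cfg.get('unadjusted_readmission_rate', float('nan')):.3f}.")
    lines.append("")
    lines.append("| model | test AUC |")
    lines.append("|---|---|")
    for m, a in report.get("auc", {}).items():
        lines.append(f"| {m} | {a:.3f} |")
    if "rsrr" in report:
        r = report["rsrr"]
        lines.append("")
        lines.append(f"Hospitals standardized: {r['n_hospitals']}; "
                     f"reclassified (any move): {r['reclassification']['pct_reclassified']}%; "
                     f"extreme-group moves: {r['reclassification']['pct_extreme_moves']}%.")
    with open(md_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
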