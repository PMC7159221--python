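"""Cohort construction from raw admission tables.

Mirrors the standard claims-analysis pipeline for condition-specific
readmission cohorts: principal-diagnosis inclusion, an ordered exclusion
cascade (zero length of stay for AMI, in-hospital death, discharge
against medical advice, December discharge with no 30-day follow-up,
transfer to acute care, age under 18, then low-volume hospitals),
first-admission selection per patient, a minimum-occurrence code filter,
comorbidity-category mapping, and an 80/10/10 train/validation/test
split stratified within hospital.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_claims import CodeUniverse

__all__ = [
    "ConditionConfig",
    "ExclusionLog",
    "Cohort",
    "ComorbidityMap",
    "apply_exclusions",
    "select_first_admission",
    "filter_rare_codes",
    "map_comorbidities",
    "split_cohort",
    "build_cohort",
    "synthetic_comorbidity_map",
    "unplanned_readmission",
]

N_COMORBIDITY_CATEGORIES = 29


class ConfigError(ValueError):
    pass


class InputError(ValueError):
    pass


@dataclass(frozen=True)
class ConditionConfig:
    """Defines one index condition: its principal-diagnosis code set and
    whether the zero-length-of-stay exclusion applies (AMI only)."""

    name: str
    principal_codes: frozenset
    exclude_zero_los: bool

    @classmethod
    def from_universe(cls, universe: CodeUniverse, name: str = "ami") -> "ConditionConfig":
        if name not in ("ami", "hf", "pna"):
            raise ConfigError(f"unknown condition {name!r}")
        return cls(name, frozenset(universe.principal_codes),
                   exclude_zero_los=(name == "ami"))


@dataclass
class ExclusionLog:
    """Ordered per-rule removal counts for one cohort build."""

    n_input: int
    steps: list[tuple[str, int]] = field(default_factory=list)
    n_final: int = 0

    def record(self, rule: str, n_removed: int) -> None:
        self.steps.append((rule, int(n_removed)))

    def check(self) -> None:
        if self.n_input - sum(n for _, n in self.steps) != self.n_final:
            raise AssertionError("exclusion log does not conserve record count")

    def to_json(self) -> str:
        return json.dumps({
            "n_input": self.n_input,
            "steps": [{"rule": r, "n_removed": n} for r, n in self.steps],
            "n_final": self.n_final,
        }, indent=2)


#: Exclusion rules in the order they are applied (after principal-dx
#: inclusion). The cascade is order-sensitive; counts are relative to the
#: survivors of the previous rule.
EXCLUSION_ORDER = ("zero_los", "died", "ama", "december", "transfer",
                   "age_under_18", "small_hospital")


def apply_exclusions(raw: pd.DataFrame, condition: ConditionConfig,
                     min_hospital_admissions: int = 10,
                     ) -> tuple[pd.DataFrame, ExclusionLog]:
    """Select the condition cohort and apply the exclusion cascade.

    Returns the surviving records and an :class:`ExclusionLog` whose
    removal counts are taken against the post-inclusion record count.
    """
    kept = raw[raw["principal_dx"].isin(condition.principal_codes)]
    log = ExclusionLog(n_input=len(kept))

    def drop(mask: np.ndarray, rule: str, df: pd.DataFrame) -> pd.DataFrame:
        log.record(rule, int(mask.sum()))
        return df[~mask]

    if condition.exclude_zero_los:
        kept = drop(kept["length_of_stay"].to_numpy() == 0, "zero_los", kept)
    else:
        log.record("zero_los", 0)
    kept = drop(kept["died"].to_numpy() == 1, "died", kept)
    kept = drop(kept["ama"].to_numpy() == 1, "ama", kept)
    kept = drop(kept["admission_month"].to_numpy() == 12, "december", kept)
    kept = drop(kept["transfer_out"].to_numpy() == 1, "transfer", kept)
    kept = drop(kept["age"].to_numpy() < 18, "age_under_18", kept)

    counts = kept.groupby("hospital_id")["hospital_id"].transform("size")
    kept = drop((counts < min_hospital_admissions).to_numpy(), "small_hospital", kept)

    log.n_final = len(kept)
    log.check()
    return kept.reset_index(drop=True), log


def select_first_admission(records: pd.DataFrame) -> pd.DataFrame:
    """Keep exactly one record per patient: the earliest admission month,
    ties broken by stable input order."""
    order = np.lexsort((np.arange(len(records)),
                        records["admission_month"].to_numpy(),
                        records["patient_id"].to_numpy()))
    first = records.iloc[order].drop_duplicates("patient_id", keep="first")
    return first.sort_index().reset_index(drop=True)


def _code_counts(records: pd.DataFrame) -> dict[str, int]:
    """Occurrence counts: one per record containing the code (presence)."""
    counts: dict[str, int] = {}
    for prin, sec, proc in zip(records["principal_dx"],
                               records["secondary_dx"],
                               records["procedures"]):
        for c in {prin, *sec, *proc}:
            counts[c] = counts.get(c, 0) + 1
    return counts


def filter_rare_codes(records: pd.DataFrame, min_count: int = 10,
                      reference: pd.DataFrame | None = None,
                      ) -> tuple[list[str], list[str], pd.DataFrame]:
    """Drop codes occurring fewer than ``min_count`` times in ``reference``.

    ``reference`` defaults to ``records`` itself; in the pipeline it is the
    full raw table, so the vocabulary reflects database-wide frequency.
    Records are never removed, only their out-of-vocabulary codes.
    Returns (dx_vocabulary, proc_vocabulary, filtered records); each
    vocabulary is ordered by decreasing count (ties by code).
    """
    if min_count < 1:
        raise ConfigError("min_count must be at least 1")
    ref = records if reference is None else reference
    counts = _code_counts(ref)
    keep = {c for c, n in counts.items() if n >= min_count}
    ordered = sorted(keep, key=lambda c: (-counts[c], c))
    dx_vocab = [c for c in ordered if not c.startswith("P")]
    proc_vocab = [c for c in ordered if c.startswith("P")]

    out = records.copy()
    out["secondary_dx"] = [[c for c in lst if c in keep]
                           for lst in records["secondary_dx"]]
    out["procedures"] = [[c for c in lst if c in keep]
                         for lst in records["procedures"]]
    return dx_vocab, proc_vocab, out


@dataclass
class ComorbidityMap:
    """Mapping from diagnosis code to one of 29 comorbidity categories.

    A pluggable two-column table (code, category index in 0..28); codes
    may map to nothing. A real Elixhauser ICD-9 table can be loaded via
    :meth:`from_table`.
    """

    mapping: dict[str, int]

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.mapping.items()
               if not (0 <= v < N_COMORBIDITY_CATEGORIES)}
        if bad:
            raise ConfigError(f"category indices out of range: {bad}")

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "ComorbidityMap":
        return cls(dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(int))))

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame({"code": list(self.mapping),
                             "category": list(self.mapping.values())})


def synthetic_comorbidity_map(universe: CodeUniverse, n_top: int = 400) -> ComorbidityMap:
    """Simplified comorbidity map for the synthetic code universe.

    The ``n_top`` most prevalent diagnosis codes map to a category derived
    from their latent cluster; rarer codes map to nothing. This emulates
    the coarse, expert-curated nature of real comorbidity indices: a
    regression on these 29 flags sees cluster-level burden but none of the
    per-code or interaction structure.
    """
    mapping: dict[str, int] = {}
    n_clusters = int(universe.dx_cluster.max()) + 1
    for rank, code in enumerate(universe.dx_codes[:n_top]):
        k = int(universe.dx_cluster[rank])
        # cluster-derived categories; alternate ranks shift so the full
        # 29-category space is used even with fewer clusters
        mapping[code] = (k + n_clusters * (rank % 2)) % N_COMORBIDITY_CATEGORIES
    return ComorbidityMap(mapping)


def map_comorbidities(records: pd.DataFrame, cmap: ComorbidityMap,
                      include_principal: bool = False) -> np.ndarray:
    """Binary (n_records x 29) comorbidity feature matrix.

    Entry (i, k) is 1 iff any secondary diagnosis code (and optionally the
    principal code) of record i maps to category k; unmapped codes
    contribute nothing.
    """
    out = np.zeros((len(records), N_COMORBIDITY_CATEGORIES), dtype=np.int8)
    for i, (prin, sec) in enumerate(zip(records["principal_dx"],
                                        records["secondary_dx"])):
        codes = list(sec) + ([prin] if include_principal else [])
        for c in codes:
            k = cmap.mapping.get(c)
            if k is not None:
                out[i, k] = 1
    return out


def split_cohort(records: pd.DataFrame,
                 proportions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                 seed: int = 0) -> np.ndarray:
    """Hospital-stratified train/validation/test assignment.

    Within each hospital, records are shuffled (seeded) and allocated to
    the three sets by largest-remainder rounding, so per-hospital
    proportions deviate from the targets by less than one record.
    Returns an array of {"train", "validation", "test"} labels aligned
    with ``records``.
    """
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ConfigError("split proportions must sum to 1")
    rng = np.random.default_rng(seed)
    labels = np.array(["train", "validation", "test"])
    out = np.empty(len(records), dtype=object)
    hosp = records["hospital_id"].to_numpy()
    for h in np.unique(hosp):
        idx = np.flatnonzero(hosp == h)
        idx = rng.permutation(idx)
        n = idx.size
        quotas = np.array([p * n for p in proportions])
        base = np.floor(quotas).astype(int)
        rem = quotas - base
        short = n - base.sum()
        for j in np.argsort(-rem, kind="stable")[:short]:
            base[j] += 1
        start = 0
        for lab, b in zip(labels, base):
            out[idx[start:start + b]] = lab
            start += b
    return out


def unplanned_readmission(records: pd.DataFrame) -> np.ndarray:
    """The modelled outcome: 30-day readmission not flagged as planned."""
    return ((records["readmit_30d"].to_numpy() == 1)
            & (records["planned_readmit"].to_numpy() == 0)).astype(np.int8)


@dataclass
class Cohort:
    """An analysis-ready cohort: records, vocabularies, split, outcome."""

    condition: str
    records: pd.DataFrame
    dx_vocabulary: list[str]
    proc_vocabulary: list[str]
    split: np.ndarray
    exclusion_log: ExclusionLog

    @property
    def y(self) -> np.ndarray:
        return unplanned_readmission(self.records)

    def indices(self, part: str) -> np.ndarray:
        return np.flatnonzero(self.split == part)


def build_cohort(raw: pd.DataFrame, condition: ConditionConfig,
                 min_code_count: int = 10, seed: int = 0,
                 reference: pd.DataFrame | None = None) -> Cohort:
    """Full cohort pipeline: exclusions, first admission, rare-code filter
    (counted over ``reference``, default the full raw table), split."""
    records, log = apply_exclusions(raw, condition)
    records = select_first_admission(records)
    dx_vocab, proc_vocab, records = filter_rare_codes(
        records, min_count=min_code_count,
        reference=raw if reference is None else reference)
    split = split_cohort(records, seed=seed)
    return Cohort(condition.name, records, dx_vocab, proc_vocab, split, log)
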