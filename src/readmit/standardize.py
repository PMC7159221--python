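"""Risk-standardized hospital readmission rates and reclassification.

Two standardization methods:

* **Predictive margin** — a hospital's rate is the average predicted
  readmission probability if *everyone in the cohort* had been admitted
  to that hospital (model-agnostic, works for any model exposing a
  forced-hospital prediction).
* **Predicted/expected ratio** — the CMS-style method for the
  hierarchical model: the hospital's mean prediction with its own
  intercept, divided by its mean population-average prediction, times
  the overall unadjusted cohort readmission rate.

Hospitals are then ranked and cut into top 20% / middle 60% / bottom 20%
groups (top = floor(0.2 N) highest rates, bottom = floor(0.2 N) lowest,
middle = remainder — the only rounding convention consistent with all
three published cohort margins), and two models' groupings are compared
by 3x3 cross-tabulation with off-diagonal reclassification percentages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .models.base import HospitalAssignment, RiskModel

__all__ = [
    "RSRRTable",
    "ReclassificationTable",
    "predictive_margin_rsrr",
    "ratio_rsrr",
    "assign_groups",
    "cross_tabulate",
    "reclassification_summary",
]

logger = logging.getLogger(__name__)

GROUPS = ("top20", "middle60", "bottom20")


class InputError(ValueError):
    pass


class UnsupportedModelError(TypeError):
    pass


@dataclass
class RSRRTable:
    """Per-hospital risk-standardized readmission rate (and group label)."""

    hospital_ids: np.ndarray
    rsrr: np.ndarray
    method: str  # predictive_margin | predicted_over_expected
    model_kind: str
    group: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.hospital_ids = np.asarray(self.hospital_ids)
        self.rsrr = np.asarray(self.rsrr, dtype=float)
        if np.any((self.rsrr <= 0) | (self.rsrr >= 1)):
            raise InputError("rsrr values must lie in (0, 1)")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"hospital_id": self.hospital_ids, "rsrr": self.rsrr})
        if self.group is not None:
            df["group"] = self.group
        return df


def predictive_margin_rsrr(model: RiskModel, inputs,
                           ) -> RSRRTable:
    """Predictive-margin standardization.

    rsrr_h = mean over all cohort records of the model's prediction with
    every record forced to hospital h. Only models carrying a hospital
    effect (HLR, ME-DS) are supported; for GBT/FFNN forcing the hospital
    cannot change any prediction and the margin is undefined as a
    hospital quality measure.
    """
    if not getattr(model, "has_hospital_effect", False):
        raise UnsupportedModelError(
            f"{model.model_kind} has no hospital effect; predictive margins "
            "are undefined for it")
    if hasattr(model, "predictive_margins"):
        ids, means = model.predictive_margins(inputs)
    else:
        ids = np.asarray(model.hospital_ids())
        means = np.array([
            model.predict(inputs, HospitalAssignment.forced(h)).mean()
            for h in ids])
    return RSRRTable(np.asarray(ids), means, "predictive_margin",
                     model.model_kind)


def ratio_rsrr(model: RiskModel, inputs, hospital_ids_per_record,
               observed_y) -> RSRRTable:
    """CMS-style predicted/expected standardization for the HLR model.

    predicted_h = mean prediction over hospital h's own records with u_h;
    expected_h = same records under the population average (u = 0);
    rsrr_h = predicted_h / expected_h x overall unadjusted rate.
    Hospitals without records are excluded with a warning.
    """
    if not getattr(model, "has_hospital_effect", False):
        raise UnsupportedModelError(
            f"{model.model_kind} has no hospital effect")
    hosp = np.asarray(hospital_ids_per_record)
    overall = float(np.mean(observed_y))
    pred_own = model.predict(inputs, HospitalAssignment.ACTUAL)
    pred_pop = model.predict(inputs, HospitalAssignment.POPULATION)
    ids, rates = [], []
    for h in model.hospital_ids():
        mask = hosp == h
        if not mask.any():
            logger.warning("hospital %r has no cohort records; excluded", h)
            continue
        ids.append(h)
        rates.append(pred_own[mask].mean() / pred_pop[mask].mean() * overall)
    return RSRRTable(np.asarray(ids), np.asarray(rates),
                     "predicted_over_expected", model.model_kind)


def assign_groups(table: RSRRTable, highest_first: bool = True) -> RSRRTable:
    """Cut hospitals into top 20% / middle 60% / bottom 20% by rate.

    "Top" means the highest risk-standardized rates by default
    (``highest_first``); ties are broken by stable hospital-id order.
    Group sizes are exactly (floor(0.2 N), N - 2 floor(0.2 N),
    floor(0.2 N)).
    """
    n = len(table.hospital_ids)
    if n < 5:
        raise InputError("need at least 5 hospitals to form quintile groups")
    key = -table.rsrr if highest_first else table.rsrr
    order = np.lexsort((table.hospital_ids, key))
    k = n // 5
    group = np.empty(n, dtype=object)
    group[order[:k]] = "top20"
    group[order[k:n - k]] = "middle60"
    group[order[n - k:]] = "bottom20"
    logger.info("group sizes: top20=%d middle60=%d bottom20=%d "
                "(top = %s rsrr)", k, n - 2 * k, k,
                "highest" if highest_first else "lowest")
    return RSRRTable(table.hospital_ids, table.rsrr, table.method,
                     table.model_kind, group)


@dataclass
class ReclassificationTable:
    """3x3 hospital counts: rows = groups under model A, cols = model B."""

    counts: np.ndarray  # (3, 3) int
    model_a: str
    model_b: str
    groups: tuple[str, ...] = GROUPS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (3, 3) or (self.counts < 0).any():
            raise InputError("counts must be a nonnegative 3x3 matrix")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=list(self.groups),
                          columns=list(self.groups))
        df["All"] = self.row_margins
        df.loc["All"] = list(self.col_margins) + [self.total]
        return df


def cross_tabulate(a: RSRRTable, b: RSRRTable) -> ReclassificationTable:
    """Cross-tabulate two models' group assignments over the same hospitals."""
    if a.group is None or b.group is None:
        raise InputError("assign_groups must be applied first")
    ids_a = {h: g for h, g in zip(a.hospital_ids, a.group)}
    ids_b = {h: g for h, g in zip(b.hospital_ids, b.group)}
    if set(ids_a) != set(ids_b):
        raise InputError("hospital sets differ between the two tables")
    gi = {g: i for i, g in enumerate(GROUPS)}
    counts = np.zeros((3, 3), dtype=np.int64)
    for h in ids_a:
        counts[gi[ids_a[h]], gi[ids_b[h]]] += 1
    return ReclassificationTable(counts, a.model_kind, b.model_kind)


def _pct_1dp(count: int, total: int) -> float:
    """100*count/total, rounded half-up to one decimal place."""
    frac = Decimal(100 * count) / Decimal(total)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def reclassification_summary(table: ReclassificationTable) -> dict:
    """Counts and percentages (one decimal, half-up) for each off-diagonal
    cell, plus the two reclassification totals: moves out of the extreme
    groups (top/bottom -> elsewhere) and all off-diagonal moves."""
    total = table.total
    if total == 0:
        raise InputError("empty reclassification table")
    cells = {}
    for i, ga in enumerate(table.groups):
        for j, gb in enumerate(table.groups):
            if i != j:
                c = int(table.counts[i, j])
                cells[f"{ga}->{gb}"] = {"count": c, "pct": _pct_1dp(c, total)}
    off_diag = total - int(np.trace(table.counts))
    extreme = int(table.counts[0, 1:].sum() + table.counts[2, :2].sum())
    return {
        "cells": cells,
        "n_reclassified": off_diag,
        "pct_reclassified": _pct_1dp(off_diag, total),
        "n_extreme_moves": extreme,
        "pct_extreme_moves": _pct_1dp(extreme, total),
        "total": total,
    }


def histogram_data(table: RSRRTable, n_bins: int = 30) -> pd.DataFrame:
    """Bin edges and counts for re-plotting the rsrr distribution exactly."""
    counts, edges = np.histogram(table.rsrr, bins=n_bins)
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                         "count": counts})
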