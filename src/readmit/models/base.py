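"""Common prediction contract for the four risk models.

Every model maps prepared inputs to readmission probabilities in (0, 1)
and is deterministic after fitting (all inference-time randomness, e.g.
dropout, is disabled). Models with a hospital effect (HLR's random
intercept, the deep set's 1-d hospital embedding) additionally support
three hospital assignments:

* ``actual`` — each record keeps its own hospital's effect;
* ``forced(h)`` — every record is scored as if admitted to hospital h
  (the basis of predictive-margin risk standardization);
* ``population`` — the hospital effect is set to its population value
  (0 for the random intercept, the mean embedding for the deep set).

GBT and FFNN carry no hospital effect and ignore the assignment.
"""

from __future__ import annotations

from abc import ABC, abstractmethod

import numpy as np


class InputError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    pass


class HospitalAssignment:
    """Hospital assignment used at prediction time."""

    ACTUAL = "actual"
    POPULATION = "population"

    @staticmethod
    def forced(hospital_id) -> tuple[str, object]:
        return ("forced", hospital_id)


def _check_probabilities(p: np.ndarray) -> np.ndarray:
    if not np.all(np.isfinite(p)):
        raise RuntimeError("model produced non-finite probabilities")
    return np.clip(p, 1e-12, 1.0 - 1e-12)


class RiskModel(ABC):
    """Fitted readmission model. ``model_kind`` is one of HLR/GBT/FFNN/ME-DS."""

    model_kind: str
    has_hospital_effect: bool = False

    @abstractmethod
    def predict(self, inputs, assignment=HospitalAssignment.ACTUAL) -> np.ndarray:
        """Readmission probabilities in (0, 1) for the prepared inputs."""

    def hospital_ids(self) -> list:
        """Hospitals known to the model (those seen at training time)."""
        raise InputError(f"{self.model_kind} has no hospital effects")
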