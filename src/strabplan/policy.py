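"""From calibrated probabilities to a physically feasible surgical plan.

Per-label decision thresholds are chosen to maximise the Matthews
correlation coefficient on held-out training predictions.  Thresholded
decisions are then passed through feasibility resolution: a muscle can never
be simultaneously recessed and resected — when both members of a pair exceed
their thresholds, the higher-probability label prevails and the alternative
dose is zeroed (exact ties keep the recession, the clinically conservative
choice).  Doses of unselected labels are zero; selected labels keep the
regression dose, floored at 0.5 mm (flagged) since a selected muscle cannot
receive a 0 mm procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import matthews_corrcoef

from .simulate import EXCLUSIVE_PAIRS, LABELS

log = logging.getLogger(__name__)

MIN_SELECTED_DOSE = 0.5  # mm


@dataclass
class ThresholdSet:
    """Per-label decision thresholds tau_j in (0, 1)."""

    thresholds: np.ndarray
    fallback: np.ndarray | None = None  # labels where 0.5 fallback was used

    def __post_init__(self):
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.fallback is None:
            self.fallback = np.zeros(len(self.thresholds), dtype=bool)


@dataclass
class PredictedPlan:
    """Calibrated probabilities, binary decisions and feasible doses."""

    probabilities: np.ndarray  # (n, 8)
    decisions: np.ndarray      # (n, 8) int
    doses: np.ndarray          # (n, 8) mm
    dose_floored: np.ndarray | None = None  # (n, 8) bool

    def to_frame(self) -> pd.DataFrame:
        data = {}
        for j, name in enumerate(LABELS):
            data[f"prob_{name}"] = self.probabilities[:, j]
            data[f"decision_{name}"] = self.decisions[:, j]
            data[f"pred_dose_{name}"] = self.doses[:, j]
        return pd.DataFrame(data)


def _best_mcc_threshold(probs: np.ndarray, labels: np.ndarray) -> float:
    """Exhaustive scan over midpoints of consecutive sorted unique
    probabilities; ties broken toward the higher threshold."""
    uniq = np.unique(probs)
    if len(uniq) < 2:
        return 0.5
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    best_tau, best_mcc = candidates[0], -np.inf
    for tau in candidates:
        m = matthews_corrcoef(labels, (probs >= tau).astype(int))
        if m > best_mcc or (m == best_mcc and tau > best_tau):
            best_mcc, best_tau = m, tau
    return float(best_tau)


def optimise_thresholds(probs: np.ndarray, labels: np.ndarray) -> ThresholdSet:
    """MCC-maximising threshold per label.

    Labels with a single class present fall back to tau = 0.5 (flagged).
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    n_labels = probs.shape[1]
    taus = np.full(n_labels, 0.5)
    fallback = np.zeros(n_labels, dtype=bool)
    for j in range(n_labels):
        y = labels[:, j]
        if y.min() == y.max():
            fallback[j] = True
            log.warning("label %s single-class: threshold fallback 0.5", LABELS[j])
            continue
        taus[j] = _best_mcc_threshold(probs[:, j], y)
    return ThresholdSet(thresholds=taus, fallback=fallback)


def resolve_conflicts(
    decisions: np.ndarray, probs: np.ndarray, doses: np.ndarray
) -> PredictedPlan:
    """Enforce feasibility on thresholded decisions.

    For each of the four recess/resect pairs, if both members are selected
    the higher-probability member is kept (exact ties keep the recession)
    and the other's decision and dose are zeroed.  Doses of all unselected
    labels are zeroed; selected labels keep their dose, floored at
    ``MIN_SELECTED_DOSE`` with a flag.
    """
    decisions = np.asarray(decisions).astype(int).copy()
    probs = np.asarray(probs, dtype=float)
    doses = np.asarray(doses, dtype=float).copy()
    squeeze = decisions.ndim == 1
    if squeeze:
        decisions, probs, doses = decisions[None], probs[None], doses[None]
    for recess_j, resect_j in EXCLUSIVE_PAIRS:
        both = (decisions[:, recess_j] == 1) & (decisions[:, resect_j] == 1)
        # ties (==) keep the recession member
        drop_recess = both & (probs[:, resect_j] > probs[:, recess_j])
        drop_resect = both & ~drop_recess
        decisions[drop_recess, recess_j] = 0
        decisions[drop_resect, resect_j] = 0
    doses = np.where(decisions == 1, doses, 0.0)
    floored = (decisions == 1) & (doses < MIN_SELECTED_DOSE)
    doses = np.where(floored, MIN_SELECTED_DOSE, doses)
    doses = np.clip(doses, 0.0, 10.0)
    if squeeze:
        decisions, probs, doses, floored = (
            decisions[0], probs[0], doses[0], floored[0],
        )
    return PredictedPlan(
        probabilities=probs, decisions=decisions, doses=doses, dose_floored=floored
    )


def assemble_plan(
    probs: np.ndarray, doses: np.ndarray, thresholds: ThresholdSet
) -> PredictedPlan:
    """decisions = (p_j >= tau_j), then feasibility resolution; idempotent."""
    probs = np.asarray(probs, dtype=float)
    decisions = (probs >= thresholds.thresholds).astype(int)
    return resolve_conflicts(decisions, probs, doses)


def check_plan_invariants(plan: PredictedPlan) -> list[str]:
    """Violation messages for the PredictedPlan invariants (empty = valid)."""
    msgs = []
    d = np.atleast_2d(plan.decisions)
    doses = np.atleast_2d(plan.doses)
    for recess_j, resect_j in EXCLUSIVE_PAIRS:
        if ((d[:, recess_j] == 1) & (d[:, resect_j] == 1)).any():
            msgs.append(
                f"simultaneous recession+resection: {LABELS[recess_j]}/{LABELS[resect_j]}"
            )
    if (doses[d == 0] != 0).any():
        msgs.append("nonzero dose on an unselected label")
    if (doses < 0).any() or (doses > 10).any():
        msgs.append("dose outside [0, 10] mm")
    return msgs
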