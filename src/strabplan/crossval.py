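"""Multilabel-stratified K-fold with a prevalence certificate, CV
orchestration and bootstrap confidence intervals.

The splitter runs iterative stratification (rarest label first) and then a
greedy swap refinement that directly minimises the certificate — the maximum
over all (fold, label) cells of |fold prevalence - overall prevalence| in
percentage points — until it meets the stated tolerance (+/- 2 points by
default).  Fold sizes differ by at most one and every patient appears in
exactly one fold, so pooling validation predictions covers the cohort once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import DOSE_COLUMNS, LABEL_COLUMNS, LABELS

log = logging.getLogger(__name__)


@dataclass
class FoldSpec:
    """A K-fold partition plus its per-(fold,label) prevalence certificate."""

    k: int
    assignment: np.ndarray          # fold index per patient
    certificate: np.ndarray         # (k, n_labels) deviations in percentage points
    tolerance: float                # stated tolerance in percentage points
    within_tolerance: bool

    @property
    def max_deviation(self) -> float:
        return float(self.certificate.max())

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"patient_id": np.arange(len(self.assignment)), "fold": self.assignment}
        )


def certificate_from_assignment(
    labels: np.ndarray, assignment: np.ndarray, k: int
) -> np.ndarray:
    """Recompute the prevalence certificate from the assignment alone."""
    labels = np.asarray(labels)
    overall = labels.mean(axis=0)
    cert = np.zeros((k, labels.shape[1]))
    for f in range(k):
        rows = assignment == f
        cert[f] = np.abs(labels[rows].mean(axis=0) - overall) * 100.0
    return cert


def _iterative_stratification(
    labels: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Iterative stratification: place examples of the currently rarest label
    into the fold with the greatest remaining desire for that label."""
    n, L = labels.shape
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    desired = sizes[:, None] * labels.sum(axis=0)[None, :] / n  # (k, L)
    capacity = sizes.astype(float).copy()
    assignment = np.full(n, -1)
    remaining = np.ones(n, dtype=bool)

    while remaining.any():
        rem_counts = labels[remaining].sum(axis=0)
        active = np.flatnonzero(rem_counts > 0)
        if len(active) == 0:
            # label-free leftovers: fill by remaining capacity
            for i in np.flatnonzero(remaining):
                f = int(np.argmax(capacity + rng.random(k) * 1e-9))
                assignment[i] = f
                capacity[f] -= 1
            break
        j = active[np.argmin(rem_counts[active])]  # rarest remaining label
        for i in np.flatnonzero(remaining & (labels[:, j] == 1)):
            score = desired[:, j] + rng.random(k) * 1e-9
            score[capacity <= 0] = -np.inf
            f = int(np.argmax(score))
            assignment[i] = f
            remaining[i] = False
            capacity[f] -= 1
            desired[f] -= labels[i]
    return assignment


def _refine_assignment(
    labels: np.ndarray,
    assignment: np.ndarray,
    k: int,
    tolerance_pp: float,
    max_iters: int = 400,
) -> np.ndarray:
    """Greedy size-preserving swaps reducing (max, mean) certificate deviation."""
    labels = np.asarray(labels, dtype=float)
    n, L = labels.shape
    assignment = assignment.copy()
    sizes = np.array([(assignment == f).sum() for f in range(k)], dtype=float)
    counts = np.zeros((k, L))
    for f in range(k):
        counts[f] = labels[assignment == f].sum(axis=0)
    overall = labels.mean(axis=0)

    def objective(cnts):
        dev = np.abs(cnts / sizes[:, None] - overall) * 100.0
        return dev.max(), dev.mean()

    for _ in range(max_iters):
        cur_max, cur_mean = objective(counts)
        if cur_max <= tolerance_pp:
            break
        dev = counts / sizes[:, None] - overall
        f_worst = int(np.argmax(np.abs(dev).max(axis=1)))
        best = None
        members_f = np.flatnonzero(assignment == f_worst)
        for g in range(k):
            if g == f_worst:
                continue
            members_g = np.flatnonzero(assignment == g)
            # evaluate swaps at the level of distinct label patterns
            pats_f = {tuple(labels[i].astype(int)): i for i in members_f}
            pats_g = {tuple(labels[i].astype(int)): i for i in members_g}
            for pf, i_f in pats_f.items():
                for pg, i_g in pats_g.items():
                    if pf == pg:
                        continue
                    delta = np.asarray(pg, dtype=float) - np.asarray(pf, dtype=float)
                    trial = counts.copy()
                    trial[f_worst] += delta
                    trial[g] -= delta
                    obj = objective(trial)
                    if obj < (cur_max, cur_mean) and (best is None or obj < best[0]):
                        best = (obj, i_f, i_g, delta)
        if best is None:
            break
        _, i_f, i_g, delta = best
        counts[f_worst] += delta
        counts[assignment[i_g]] -= delta
        assignment[i_f], assignment[i_g] = assignment[i_g], f_worst
    return assignment


def multilabel_stratified_kfold(
    labels: np.ndarray,
    k: int = 10,
    tolerance: float = 2.0,
    seed: int = 0,
    retry_budget: int = 50,
) -> FoldSpec:
    """Multilabel-stratified K-fold keeping every (fold, label) prevalence
    within ``tolerance`` percentage points of the overall prevalence.

    Iterative-stratification assignment followed by swap refinement; retried
    with new sub-seeds up to ``retry_budget`` and the best-found split is
    returned (flagged if it still exceeds the tolerance).
    """
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError("labels must be an n x L binary matrix")
    n, L = labels.shape
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if n < k:
        raise ValueError(f"need at least k={k} patients, got {n}")

    ss = np.random.SeedSequence(seed)
    best: FoldSpec | None = None
    for child in ss.spawn(max(retry_budget, 1)):
        rng = np.random.default_rng(child)
        assignment = _iterative_stratification(labels, k, rng)
        assignment = _refine_assignment(labels, assignment, k, tolerance)
        cert = certificate_from_assignment(labels, assignment, k)
        spec = FoldSpec(
            k=k,
            assignment=assignment,
            certificate=cert,
            tolerance=tolerance,
            within_tolerance=bool(cert.max() <= tolerance),
        )
        if best is None or spec.max_deviation < best.max_deviation:
            best = spec
        if best.within_tolerance:
            return best
    log.warning(
        "stratified split exceeds tolerance after %d retries: max deviation "
        "%.2f pp", retry_budget, best.max_deviation,
    )
    return best


@dataclass
class CrossValidationResults:
    """Pooled out-of-fold predictions and per-fold fitted artefacts."""

    oof: pd.DataFrame
    foldspec: FoldSpec
    fold_results: list

    def metrics_report(self, cohort: pd.DataFrame, bootstrap_b: int = 1000, seed: int = 0):
        from .evaluation import full_report

        return full_report(self.oof, cohort, bootstrap_b=bootstrap_b, seed=seed)

    def summary(self) -> str:
        from .evaluation import quick_summary

        lines = [
            "Multilabel-stratified cross-validation",
            f"  folds: {self.foldspec.k}   patients: {len(self.oof)}",
            f"  certificate max deviation: {self.foldspec.max_deviation:.2f} pp "
            f"(tolerance {self.foldspec.tolerance:g} pp)",
            quick_summary(self.oof),
        ]
        return "\n".join(lines)


def run_cv(
    cohort: pd.DataFrame,
    model_config=None,
    k: int = 10,
    seed: int = 0,
    tolerance: float = 2.0,
) -> CrossValidationResults:
    """Leakage-free K-fold cross-validation of the full planning pipeline.

    For each fold, preprocessing statistics, the network, calibration and
    thresholds are fitted on the training folds only (calibration and
    thresholds on an inner held-out split of the training data); out-of-fold
    predictions cover every patient exactly once.  Per-fold seeds derive
    deterministically from ``seed``.
    """
    from .model import SurgicalPlanModel

    labels = cohort[LABEL_COLUMNS].to_numpy()
    spec = multilabel_stratified_kfold(labels, k=k, tolerance=tolerance, seed=seed)
    fold_seeds = [int(s) for s in
                  np.random.SeedSequence(seed).generate_state(k) % (2 ** 31)]

    pieces = []
    fold_results = []
    for f in range(k):
        val_idx = spec.fold_indices(f)
        train_idx = np.flatnonzero(spec.assignment != f)
        train_df = cohort.iloc[train_idx]
        val_df = cohort.iloc[val_idx]
        model = SurgicalPlanModel.from_dataframe(train_df, config=model_config)
        res = model.fit(seed=fold_seeds[f])
        plan = res.predict(val_df)
        piece = plan.to_frame()
        piece.insert(0, "fold", f)
        piece.insert(0, "patient_id", val_df["patient_id"].to_numpy())
        for col in LABEL_COLUMNS + DOSE_COLUMNS:
            piece[col] = val_df[col].to_numpy()
        piece["deviation_angle"] = val_df["deviation_angle"].to_numpy()
        pieces.append(piece)
        fold_results.append(res)
        log.info(
            "fold %d/%d: n_val=%d best_epoch=%d", f + 1, k, len(val_idx),
            res.training_log["best_epoch"],
        )
    oof = (
        pd.concat(pieces, ignore_index=True)
        .sort_values("patient_id")
        .reset_index(drop=True)
    )
    return CrossValidationResults(oof=oof, foldspec=spec, fold_results=fold_results)


def bootstrap_ci(
    statistic,
    data,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float, float]:
    """Percentile bootstrap over rows (patients).

    ``statistic`` maps the data (DataFrame or array) to a scalar; resamples
    on which it is undefined (raises or returns NaN) are redrawn, with the
    redraw count logged.  Returns (point, lower, upper).
    """
    n = len(data)
    if n == 0:
        raise ValueError("data must be non-empty")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)

    def take(idx):
        if isinstance(data, pd.DataFrame):
            return data.iloc[idx]
        return np.asarray(data)[idx]

    point = float(statistic(take(np.arange(n))))
    draws = []
    redraws = 0
    while len(draws) < B:
        idx = rng.integers(0, n, size=n)
        try:
            val = float(statistic(take(idx)))
        except Exception:
            val = float("nan")
        if np.isfinite(val):
            draws.append(val)
        else:
            redraws += 1
            if redraws > 50 * B:
                raise RuntimeError("statistic undefined on almost all resamples")
    if redraws:
        log.info("bootstrap redrew %d degenerate resamples", redraws)
    lo, hi = np.percentile(draws, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return point, float(lo), float(hi)
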