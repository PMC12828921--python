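"""Evaluation battery for the planning pipeline.

Discrimination (per-label and macro AUC/F1/MCC, exact-match accuracy),
calibration (ECE, slope), dose accuracy (MAE/RMSE/R-squared,
fraction-within-tolerance, Bland-Altman limits of agreement), tiered
plan-agreement rates against the reference plans, decision-curve net
benefit, subgroup fairness by strabismus type, and permutation feature
importance.  Headline metrics carry percentile-bootstrap confidence
intervals resampled at the patient level (preserving the within-patient
correlation of the eight outputs).
"""

from __future__ import annotations

import json
import logging

import numpy as np
import pandas as pd
from sklearn.metrics import (
    f1_score,
    matthews_corrcoef,
    r2_score,
    roc_auc_score,
)

from .calibration import calibration_slope, ece, reliability_table
from .crossval import bootstrap_ci
from .preprocess import FEATURES
from .simulate import DOSE_COLUMNS, LABEL_COLUMNS, LABELS

log = logging.getLogger(__name__)

PROB_COLUMNS = [f"prob_{name}" for name in LABELS]
DECISION_COLUMNS = [f"decision_{name}" for name in LABELS]
PRED_DOSE_COLUMNS = [f"pred_dose_{name}" for name in LABELS]

DOSE_TOLERANCE_MM = 0.30   # fraction-within tolerance
DOSE_QUANTUM_MM = 0.5      # surgeons plan in 0.5 mm steps


def classification_metrics(
    probs: np.ndarray, decisions: np.ndarray, labels: np.ndarray
) -> dict:
    """Per-label and macro AUC / F1 / MCC plus exact-match accuracy.

    AUC is the Mann-Whitney rank statistic (tie-corrected); single-class
    labels get AUC NaN and are excluded from the macro mean with a note.
    Exact match is the fraction of patients whose full 8-bit decision vector
    equals the reference; the majority baseline is the frequency of the
    modal reference vector.
    """
    probs = np.asarray(probs, dtype=float)
    decisions = np.asarray(decisions, dtype=int)
    labels = np.asarray(labels, dtype=int)
    per_label = []
    undefined = []
    for j, name in enumerate(LABELS):
        y = labels[:, j]
        if y.min() == y.max():
            auc = float("nan")
            undefined.append(name)
        else:
            auc = float(roc_auc_score(y, probs[:, j]))
        per_label.append(
            {
                "label": name,
                "auc": auc,
                "f1": float(f1_score(y, decisions[:, j], zero_division=0)),
                "mcc": float(matthews_corrcoef(y, decisions[:, j])),
                "prevalence": float(y.mean()),
            }
        )
    aucs = [m["auc"] for m in per_label if np.isfinite(m["auc"])]
    exact = float((decisions == labels).all(axis=1).mean())
    vectors, counts = np.unique(labels, axis=0, return_counts=True)
    majority = float(counts.max() / len(labels))
    return {
        "per_label": per_label,
        "macro_auc": float(np.mean(aucs)) if aucs else float("nan"),
        "macro_f1": float(np.mean([m["f1"] for m in per_label])),
        "macro_mcc": float(np.mean([m["mcc"] for m in per_label])),
        "exact_match": exact,
        "majority_baseline": majority,
        "undefined_auc_labels": undefined,
    }


def regression_metrics(
    pred: np.ndarray, true: np.ndarray, tolerance: float = DOSE_TOLERANCE_MM
) -> dict:
    """MAE, RMSE, R-squared and fraction within +/- tolerance (mm)."""
    pred = np.asarray(pred, dtype=float).ravel()
    true = np.asarray(true, dtype=float).ravel()
    if pred.shape != true.shape:
        raise ValueError("prediction/truth vectors must align")
    err = pred - true
    out = {
        "mae": float(np.abs(err).mean()),
        "rmse": float(np.sqrt((err ** 2).mean())),
        "fraction_within_tolerance": float((np.abs(err) <= tolerance).mean()),
        "tolerance_mm": tolerance,
        "n": int(len(pred)),
    }
    if np.ptp(true) == 0:
        out["r2"] = float("nan")
        out["r2_undefined"] = True
    else:
        out["r2"] = float(r2_score(true, pred))
    return out


def bland_altman(pred: np.ndarray, true: np.ndarray) -> dict:
    """Bias and 95% limits of agreement (bias +/- 1.96 * sample SD)."""
    d = np.asarray(pred, dtype=float).ravel() - np.asarray(true, dtype=float).ravel()
    if len(d) < 2:
        raise ValueError("Bland-Altman needs at least 2 paired values")
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return {
        "bias": bias,
        "loa_lower": bias - 1.96 * sd,
        "loa_upper": bias + 1.96 * sd,
        "sd_diff": sd,
    }


def plan_agreement(
    pred_decisions: np.ndarray,
    pred_doses: np.ndarray,
    true_labels: np.ndarray,
    true_doses: np.ndarray,
    quantum: float = DOSE_QUANTUM_MM,
) -> dict:
    """Tiered whole-plan agreement rates.

    Tier 1: identical decision vector and every operated dose within the
    rounding quantum (0.5 mm, the surgeon's planning step).  Tier 2:
    identical decisions, exactly one muscle deviating by more than the
    quantum but at most 1 mm, all others within the quantum.  "Clinically
    acceptable" = tier 1 + tier 2.  The majority baseline is the frequency
    of the modal reference decision vector.
    """
    pred_decisions = np.asarray(pred_decisions, dtype=int)
    true_labels = np.asarray(true_labels, dtype=int)
    pred_doses = np.asarray(pred_doses, dtype=float)
    true_doses = np.asarray(true_doses, dtype=float)
    n = len(true_labels)
    same_decisions = (pred_decisions == true_labels).all(axis=1)
    operated = true_labels == 1
    dose_err = np.abs(pred_doses - true_doses)
    err_op = np.where(operated, dose_err, 0.0)
    within_q = np.where(operated, err_op <= quantum, True)
    over_q_under_1 = operated & (err_op > quantum) & (err_op <= 1.0)
    tier1 = same_decisions & within_q.all(axis=1)
    tier2 = (
        same_decisions
        & ~tier1
        & (over_q_under_1.sum(axis=1) == 1)
        & ((~within_q).sum(axis=1) == 1)
    )
    vectors, counts = np.unique(true_labels, axis=0, return_counts=True)
    return {
        "tier1_exact": float(tier1.mean()),
        "tier2_within_1mm": float(tier2.mean()),
        "clinically_acceptable": float((tier1 | tier2).mean()),
        "decision_vector_match": float(same_decisions.mean()),
        "majority_baseline": float(counts.max() / n),
        "quantum_mm": quantum,
    }


def decision_curve(
    probs: np.ndarray,
    labels: np.ndarray,
    thresholds: np.ndarray | None = None,
) -> pd.DataFrame:
    """Net-benefit table for the model vs treat-all / treat-none strategies.

    NB(p_t) = TP/n - (FP/n) * p_t / (1 - p_t) with positives decided by
    p >= p_t; treat-all decides positive everywhere; treat-none is 0.
    """
    probs = np.asarray(probs, dtype=float).ravel()
    labels = np.asarray(labels, dtype=int).ravel()
    if thresholds is None:
        thresholds = np.arange(0.05, 0.96, 0.05)
    thresholds = np.asarray(thresholds, dtype=float)
    if ((thresholds <= 0) | (thresholds >= 1)).any():
        raise ValueError("threshold grid must lie strictly inside (0, 1)")
    n = len(labels)
    prevalence = labels.mean()
    rows = []
    for pt in thresholds:
        w = pt / (1.0 - pt)
        pos = probs >= pt
        tp = float((pos & (labels == 1)).sum())
        fp = float((pos & (labels == 0)).sum())
        rows.append(
            {
                "threshold": float(pt),
                "nb_model": tp / n - (fp / n) * w,
                "nb_treat_all": prevalence - (1 - prevalence) * w,
                "nb_treat_none": 0.0,
            }
        )
    return pd.DataFrame(rows)


def _operated_mask(true_doses: np.ndarray) -> np.ndarray:
    # truly operated = recorded dose > 0 (flip-on label noise keeps dose 0)
    return np.asarray(true_doses) > 0


def subgroup_report(oof: pd.DataFrame) -> dict:
    """Classification and regression metrics within the exotropia and
    esotropia strata, plus the absolute gap per headline metric."""
    out = {}
    strata = {
        "exotropia": oof["deviation_angle"] > 0,
        "esotropia": oof["deviation_angle"] < 0,
    }
    for name, mask in strata.items():
        sub = oof[mask]
        if len(sub) == 0:
            log.warning("empty stratum %s skipped", name)
            continue
        cls = classification_metrics(
            sub[PROB_COLUMNS].to_numpy(),
            sub[DECISION_COLUMNS].to_numpy(),
            sub[LABEL_COLUMNS].to_numpy(),
        )
        true_d = sub[DOSE_COLUMNS].to_numpy()
        pred_d = sub[PRED_DOSE_COLUMNS].to_numpy()
        op = _operated_mask(true_d)
        reg = regression_metrics(pred_d[op], true_d[op])
        out[name] = {
            "n": int(len(sub)),
            "macro_auc": cls["macro_auc"],
            "macro_f1": cls["macro_f1"],
            "mae_operated": reg["mae"],
        }
    if len(out) == 2:
        out["gap"] = {
            key: abs(out["exotropia"][key] - out["esotropia"][key])
            for key in ("macro_auc", "macro_f1", "mae_operated")
        }
    return out


def permutation_importance(
    results,
    df: pd.DataFrame,
    metric: str = "macro_auc",
    n_repeats: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Model-agnostic feature attribution: degradation of ``metric`` when one
    raw feature column is permuted, mean +/- SD over repeats, ranked
    descending.

    ``results`` is a fitted `SurgicalPlanResults`; the permutation runs
    through its full predict path so derived features inherit the shuffle.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    labels = df[LABEL_COLUMNS].to_numpy()
    doses = df[DOSE_COLUMNS].to_numpy()

    def score(frame):
        plan = results.predict(frame)
        if metric == "macro_auc":
            return classification_metrics(
                plan.probabilities, plan.decisions, labels
            )["macro_auc"]
        if metric == "dose_mae":
            op = _operated_mask(doses)
            return -regression_metrics(plan.doses[op], doses[op])["mae"]
        raise ValueError(f"unknown metric {metric!r}")

    # permute raw columns; derived features recomputed inside predict
    raw_by_feature = {
        "age": ["age"],
        "deviating_eye": ["deviating_eye"],
        "deviation_angle": ["deviation_angle"],
        "al_mean": ["axial_length_od", "axial_length_os"],
        "al_diff": ["axial_length_od", "axial_length_os"],
        "se_mean": ["se_od", "se_os"],
        "se_diff": ["se_od", "se_os"],
        "bcva_od": ["bcva_od"],
        "bcva_os": ["bcva_os"],
        "equal_vision": ["equal_vision"],
    }
    base = score(df)
    rows = []
    for feature in FEATURES:
        drops = []
        for _ in range(n_repeats):
            shuffled = df.copy()
            perm = rng.permutation(len(df))
            for col in raw_by_feature[feature]:
                shuffled[col] = shuffled[col].to_numpy()[perm]
            drops.append(base - score(shuffled))
        rows.append(
            {
                "feature": feature,
                "importance_mean": float(np.mean(drops)),
                "importance_sd": float(np.std(drops)),
            }
        )
    table = pd.DataFrame(rows).sort_values(
        "importance_mean", ascending=False, ignore_index=True
    )
    table.attrs["baseline_score"] = base
    return table


def _per_fold_regression(oof: pd.DataFrame) -> dict:
    """Operated-dose metrics per fold, plus their across-fold mean and SD
    (the pooled value is reported separately)."""
    if "fold" not in oof.columns:
        return {}
    rows = []
    for f, sub in oof.groupby("fold"):
        td = sub[DOSE_COLUMNS].to_numpy()
        pdos = sub[PRED_DOSE_COLUMNS].to_numpy()
        op = _operated_mask(td)
        if not op.any():
            continue
        m = regression_metrics(pdos[op], td[op])
        rows.append({"fold": int(f), "mae": m["mae"], "rmse": m["rmse"], "r2": m["r2"]})
    if not rows:
        return {}
    out = {"folds": rows}
    for key in ("mae", "rmse", "r2"):
        vals = np.array([r[key] for r in rows])
        vals = vals[np.isfinite(vals)]
        out[f"{key}_fold_mean"] = float(vals.mean())
        out[f"{key}_fold_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return out


def full_report(
    oof: pd.DataFrame,
    cohort: pd.DataFrame | None = None,
    bootstrap_b: int = 1000,
    seed: int = 0,
) -> dict:
    """Assemble the MetricsReport dict from pooled out-of-fold predictions."""
    probs = oof[PROB_COLUMNS].to_numpy()
    decisions = oof[DECISION_COLUMNS].to_numpy()
    labels = oof[LABEL_COLUMNS].to_numpy()
    pred_doses = oof[PRED_DOSE_COLUMNS].to_numpy()
    true_doses = oof[DOSE_COLUMNS].to_numpy()
    operated = _operated_mask(true_doses)

    report = {
        "classification": classification_metrics(probs, decisions, labels),
        "calibration": {
            "ece_pooled": ece(probs.ravel(), labels.ravel()),
            "slope_pooled": calibration_slope(probs.ravel(), labels.ravel()),
        },
        "regression_all_slots": regression_metrics(pred_doses, true_doses),
        "regression_operated": regression_metrics(
            pred_doses[operated], true_doses[operated]
        ),
        "bland_altman_all_slots": bland_altman(pred_doses, true_doses),
        "bland_altman_operated": bland_altman(
            pred_doses[operated], true_doses[operated]
        ),
        "plan_agreement": plan_agreement(decisions, pred_doses, labels, true_doses),
        "regression_by_fold": _per_fold_regression(oof),
        "subgroups": subgroup_report(oof),
        "decision_curve": decision_curve(probs.ravel(), labels.ravel()).to_dict(
            "records"
        ),
        "reliability": reliability_table(probs.ravel(), labels.ravel()).to_dict(
            "records"
        ),
    }

    if bootstrap_b and bootstrap_b > 0:
        def macro_auc_stat(sub):
            return classification_metrics(
                sub[PROB_COLUMNS].to_numpy(),
                sub[DECISION_COLUMNS].to_numpy(),
                sub[LABEL_COLUMNS].to_numpy(),
            )["macro_auc"]

        def mae_stat(sub):
            td = sub[DOSE_COLUMNS].to_numpy()
            pdos = sub[PRED_DOSE_COLUMNS].to_numpy()
            op = _operated_mask(td)
            return float(np.abs(pdos[op] - td[op]).mean())

        def exact_stat(sub):
            return float(
                (sub[DECISION_COLUMNS].to_numpy() == sub[LABEL_COLUMNS].to_numpy())
                .all(axis=1)
                .mean()
            )

        def ece_stat(sub):
            return ece(
                sub[PROB_COLUMNS].to_numpy().ravel(),
                sub[LABEL_COLUMNS].to_numpy().ravel(),
            )

        cis = {}
        for name, stat in [
            ("macro_auc", macro_auc_stat),
            ("mae_operated", mae_stat),
            ("exact_match", exact_stat),
            ("ece_pooled", ece_stat),
        ]:
            point, lo, hi = bootstrap_ci(stat, oof, B=bootstrap_b, seed=seed)
            cis[name] = {"point": point, "lower": lo, "upper": hi}
        report["bootstrap_ci"] = cis
        report["bootstrap_b"] = bootstrap_b
    return report


def quick_summary(oof: pd.DataFrame) -> str:
    cls = classification_metrics(
        oof[PROB_COLUMNS].to_numpy(),
        oof[DECISION_COLUMNS].to_numpy(),
        oof[LABEL_COLUMNS].to_numpy(),
    )
    true_d = oof[DOSE_COLUMNS].to_numpy()
    pred_d = oof[PRED_DOSE_COLUMNS].to_numpy()
    op = _operated_mask(true_d)
    reg = regression_metrics(pred_d[op], true_d[op])
    cal = ece(oof[PROB_COLUMNS].to_numpy().ravel(), oof[LABEL_COLUMNS].to_numpy().ravel())
    return (
        f"  macro-AUC {cls['macro_auc']:.3f}   macro-F1 {cls['macro_f1']:.3f}   "
        f"exact match {cls['exact_match']:.1%}\n"
        f"  operated-dose MAE {reg['mae']:.3f} mm   RMSE {reg['rmse']:.3f} mm   "
        f"R^2 {reg['r2']:.3f}\n"
        f"  pooled ECE {cal:.4f}"
    )


def report_to_markdown(report: dict) -> str:
    """Render the MetricsReport as a human-readable Markdown document."""
    cls = report["classification"]
    lines = [
        "# Metrics report",
        "",
        "## Muscle selection (classification)",
        "",
        "| label | AUC | F1 | MCC | prevalence |",
        "|---|---|---|---|---|",
    ]
    for m in cls["per_label"]:
        auc = f"{m['auc']:.3f}" if np.isfinite(m["auc"]) else "undefined"
        lines.append(
            f"| {m['label']} | {auc} | {m['f1']:.3f} | {m['mcc']:.3f} "
            f"| {m['prevalence']:.3f} |"
        )
    lines += [
        f"| **macro** | **{cls['macro_auc']:.3f}** | **{cls['macro_f1']:.3f}** "
        f"| **{cls['macro_mcc']:.3f}** | |",
        "",
        f"Exact-match accuracy: **{cls['exact_match']:.1%}** "
        f"(majority baseline {cls['majority_baseline']:.1%})",
        "",
        "## Calibration",
        "",
        f"Pooled ECE: **{report['calibration']['ece_pooled']:.4f}**; "
        f"calibration slope: {report['calibration']['slope_pooled']:.3f}",
        "",
        "## Dose regression",
        "",
    ]
    for scope in ("regression_operated", "regression_all_slots"):
        r = report[scope]
        label = "operated muscles" if scope == "regression_operated" else "all 8 slots"
        r2 = f"{r['r2']:.3f}" if np.isfinite(r.get("r2", np.nan)) else "undefined"
        lines.append(
            f"- {label}: MAE {r['mae']:.3f} mm, RMSE {r['rmse']:.3f} mm, "
            f"R^2 {r2}, within +/-{r['tolerance_mm']:.2f} mm: "
            f"{r['fraction_within_tolerance']:.1%} (n={r['n']})"
        )
    ba = report["bland_altman_operated"]
    lines += [
        "",
        f"Bland-Altman (operated): bias {ba['bias']:+.3f} mm, 95% LoA "
        f"[{ba['loa_lower']:+.3f}, {ba['loa_upper']:+.3f}] mm",
        "",
        "## Whole-plan agreement",
        "",
    ]
    pa = report["plan_agreement"]
    lines += [
        f"- Tier 1 (exact, doses within {pa['quantum_mm']:.1f} mm): "
        f"{pa['tier1_exact']:.1%}",
        f"- Tier 2 (one muscle off by <= 1 mm): {pa['tier2_within_1mm']:.1%}",
        f"- Clinically acceptable: {pa['clinically_acceptable']:.1%} "
        f"(majority baseline {pa['majority_baseline']:.1%})",
    ]
    if "subgroups" in report and "gap" in report.get("subgroups", {}):
        sg = report["subgroups"]
        lines += [
            "",
            "## Subgroups (strabismus type)",
            "",
            f"- exotropia (n={sg['exotropia']['n']}): macro-AUC "
            f"{sg['exotropia']['macro_auc']:.3f}, operated MAE "
            f"{sg['exotropia']['mae_operated']:.3f} mm",
            f"- esotropia (n={sg['esotropia']['n']}): macro-AUC "
            f"{sg['esotropia']['macro_auc']:.3f}, operated MAE "
            f"{sg['esotropia']['mae_operated']:.3f} mm",
            f"- gaps: AUC {sg['gap']['macro_auc']:.3f}, MAE "
            f"{sg['gap']['mae_operated']:.3f} mm",
        ]
    if "bootstrap_ci" in report:
        lines += ["", "## Bootstrap 95% CIs", ""]
        for name, ci in report["bootstrap_ci"].items():
            lines.append(
                f"- {name}: {ci['point']:.4f} [{ci['lower']:.4f}, {ci['upper']:.4f}]"
            )
    return "\n".join(lines) + "\n"


def report_to_json(report: dict, path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=default)
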