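"""Standard figures: ROC panel, reliability diagram, Bland-Altman, residuals,
decision curve, permutation importance.  All functions return a matplotlib
Figure; `save_standard_plots` writes PNGs into a run directory."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .evaluation import (
    DECISION_COLUMNS,
    DOSE_COLUMNS,
    LABEL_COLUMNS,
    PRED_DOSE_COLUMNS,
    PROB_COLUMNS,
)
from .simulate import LABELS


def roc_panel(oof: pd.DataFrame):
    fig, ax = plt.subplots(figsize=(6, 6))
    for j, name in enumerate(LABELS):
        y = oof[LABEL_COLUMNS[j]].to_numpy()
        p = oof[PROB_COLUMNS[j]].to_numpy()
        if y.min() == y.max():
            continue
        fpr, tpr, _ = roc_curve(y, p)
        ax.plot(fpr, tpr, lw=1.2, label=f"{name} (AUC {roc_auc_score(y, p):.3f})")
    ax.plot([0, 1], [0, 1], "--", color="grey", lw=1)
    ax.set_xlabel("false-positive rate")
    ax.set_ylabel("true-positive rate")
    ax.legend(fontsize=7)
    ax.set_title("Muscle-selection ROC curves (pooled out-of-fold)")
    return fig

def reliability_diagram(report: dict):
    table = pd.DataFrame(report["reliability"])
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot([0, 1], [0, 1], "--", color="grey", lw=1)
    ax.plot(table["mean_predicted"], table["observed_rate"], "o-", color="C0")
    ece = report["calibration"]["ece_pooled"]
    ax.set_xlabel("mean predicted probability (decile bins)")
    ax.set_ylabel("observed event rate")
    ax.set_title(f"Reliability after temperature + beta calibration (ECE {ece:.4f})")
    return fig

def bland_altman_plot(oof: pd.DataFrame, report: dict):
    pred = oof[PRED_DOSE_COLUMNS].to_numpy().ravel()
    true = oof[DOSE_COLUMNS].to_numpy().ravel()
    ba = report["bland_altman_all_slots"]
    mean = (pred + true) / 2
    diff = pred - true
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(mean, diff, s=4, alpha=0.3)
    ax.axhline(ba["bias"], color="red", ls="--", lw=1)
    for key in ("loa_lower", "loa_upper"):
        ax.axhline(ba[key], color="grey", ls="--", lw=1)
    ax.set_xlabel("mean of predicted and recorded dose (mm)")
    ax.set_ylabel("difference (mm)")
    ax.set_title("Bland-Altman: dose predictions (all slots)")
    return fig

def residual_plot(oof: pd.DataFrame):
    pred = oof[PRED_DOSE_COLUMNS].to_numpy()
    true = oof[DOSE_COLUMNS].to_numpy()
    operated = true > 0
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(pred[operated], (pred - true)[operated], s=5, alpha=0.4)
    ax.axhline(0, ls="--", color="grey")
    ax.set_xlabel("predicted dose (mm)")
    ax.set_ylabel("residual (mm)")
    ax.set_title("Dose residuals, operated muscles")
    return fig

def decision_curve_plot(report: dict):
    table = pd.DataFrame(report["decision_curve"])
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(table["threshold"], table["nb_model"], label="model", color="C0")
    ax.plot(table["threshold"], table["nb_treat_all"], "--", label="treat all", color="C1")
    ax.plot(table["threshold"], table["nb_treat_none"], ":", label="treat none", color="C2")
    ax.set_ylim(bottom=max(-0.05, table["nb_treat_all"].min() - 0.02))
    ax.set_xlabel("threshold probability")
    ax.set_ylabel("net benefit")
    ax.legend()
    ax.set_title("Decision-curve analysis (pooled labels)")
    return fig

def importance_plot(table: pd.DataFrame):
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.barh(table["feature"][::-1], table["importance_mean"][::-1],
            xerr=table["importance_sd"][::-1])
    ax.set_xlabel("macro-AUC degradation when permuted")
    ax.set_title("Permutation feature importance")
    fig.tight_layout()
    return fig

def save_standard_plots(oof: pd.DataFrame, report: dict, out_dir) -> list[str]:
    out = Path(out_dir)
    written = []
    for name, fig in [
        ("roc.png", roc_panel(oof)),
        ("reliability.png", reliability_diagram(report)),
        ("bland_altman.png", bland_altman_plot(oof, report)),
        ("residuals.png", residual_plot(oof)),
        ("decision_curve.png", decision_curve_plot(report)),
    ]:
        fig.savefig(out / name, dpi=120)
        plt.close(fig)
        written.append(name)
    return written
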