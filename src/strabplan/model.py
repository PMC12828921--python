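"""Model and Results objects for the surgical planning network.

`SurgicalPlanModel` is constructed from a cohort DataFrame (statsmodels
style); `fit()` trains the full planning stack on the model's data —
winsorise/standardise, train the multi-task network with early stopping on
an inner held-out split, fit temperature + beta calibration and MCC-optimal
thresholds on that inner split's out-of-sample predictions — and returns a
`SurgicalPlanResults` carrying the fitted parameters, calibration,
thresholds, training log and a `summary()` table.  `random_search` tunes
hyper-parameters by inner-fold validation loss.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import yaml

from . import preprocess
from .calibration import CalibrationParams, apply_calibration, fit_calibration
from .crossval import multilabel_stratified_kfold
from .nn import LossWeights, ModelConfig, MultiTaskNet
from .policy import PredictedPlan, ThresholdSet, assemble_plan, optimise_thresholds
from .preprocess import FEATURES, PreprocessStats
from .simulate import DOSE_COLUMNS, LABEL_COLUMNS, LABELS

log = logging.getLogger(__name__)

#: labels with fewer inner-split positives than this share calibration params
SHARED_CALIBRATION_MIN_POS = 20


class SurgicalPlanModel:
    """Multi-task surgical planning model bound to a training cohort.

    Parameters
    ----------
    features : DataFrame of raw predictor columns (simulator schema)
    labels : (n, 8) binary muscle-procedure matrix
    doses : (n, 8) dose matrix in mm (0 for unoperated muscles)
    config : ModelConfig, architecture/optimisation hyper-parameters
    """

    def __init__(self, features: pd.DataFrame, labels, doses, config: ModelConfig | None = None):
        self.features = features.reset_index(drop=True)
        self.labels = np.asarray(labels, dtype=int)
        self.doses = np.asarray(doses, dtype=float)
        if self.labels.shape != self.doses.shape or self.labels.shape[1] != 8:
            raise ValueError("labels and doses must both be (n, 8)")
        self.config = config or ModelConfig()
        self.config = replace(self.config, input_width=len(FEATURES))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, config: ModelConfig | None = None):
        """Build the model from a cohort table in the simulator CSV schema."""
        return cls(
            features=df,
            labels=df[LABEL_COLUMNS].to_numpy(),
            doses=df[DOSE_COLUMNS].to_numpy(),
            config=config,
        )

    def fit(
        self,
        seed: int | None = None,
        inner_val_fraction: float = 0.2,
        calibrate: bool = True,
    ) -> "SurgicalPlanResults":
        """Train the planning stack on this model's data.

        An inner multilabel-stratified split holds out
        ``inner_val_fraction`` of the rows; the network early-stops on the
        held-out loss, and calibration and thresholds are fitted on the
        held-out out-of-sample predictions, so nothing downstream ever sees
        its own training targets.
        """
        cfg = self.config if seed is None else replace(self.config, seed=int(seed))
        feats = preprocess.derive_features(self.features)
        stats = preprocess.fit_winsor_standardise(feats)
        X = preprocess.transform(feats, stats)

        k_inner = max(2, round(1.0 / inner_val_fraction))
        inner = multilabel_stratified_kfold(
            self.labels, k=min(k_inner, len(X)), tolerance=5.0, seed=cfg.seed
        )
        val_rows = inner.fold_indices(0)
        train_rows = np.flatnonzero(inner.assignment != 0)

        weights = LossWeights.from_labels(self.labels[train_rows], lam=cfg.loss_lambda)
        # several independent initialisations; keep the best by held-out loss
        init_seeds = [
            int(s) for s in
            np.random.SeedSequence(cfg.seed).generate_state(max(cfg.n_init, 1))
            % (2 ** 31)
        ]
        net, training_log = None, None
        for s in init_seeds:
            cand = MultiTaskNet(replace(cfg, seed=s))
            cand_log = cand.train(
                X[train_rows], self.labels[train_rows], self.doses[train_rows],
                X[val_rows], self.labels[val_rows], self.doses[val_rows],
                weights=weights,
            )
            if training_log is None or cand_log["best_val_loss"] < training_log["best_val_loss"]:
                net, training_log = cand, cand_log

        inner_logits, _ = net.predict_logits(X[val_rows])
        inner_labels = self.labels[val_rows]
        calibrations = _fit_per_label_calibration(
            inner_logits, inner_labels, enabled=calibrate
        )
        inner_probs = _apply_per_label(inner_logits, calibrations)
        thresholds = optimise_thresholds(inner_probs, inner_labels)

        return SurgicalPlanResults(
            model=self,
            config=cfg,
            net=net,
            stats=stats,
            calibrations=calibrations,
            thresholds=thresholds,
            training_log=training_log,
            loss_weights=weights,
        )


def _fit_per_label_calibration(
    logits: np.ndarray, labels: np.ndarray, enabled: bool = True
) -> list[CalibrationParams]:
    """Per-label temperature + beta calibration; rare labels (< 20 positives
    on the calibration split) and single-class labels share parameters
    fitted on all labels pooled."""
    n_labels = logits.shape[1]
    identity = CalibrationParams()
    if not enabled:
        return [identity] * n_labels
    pooled = fit_calibration(logits.ravel(), labels.ravel())
    out = []
    for j in range(n_labels):
        y = labels[:, j]
        if y.min() == y.max() or y.sum() < SHARED_CALIBRATION_MIN_POS:
            out.append(pooled)
            continue
        try:
            out.append(fit_calibration(logits[:, j], y))
        except Exception:
            out.append(pooled)
    return out


def _apply_per_label(logits: np.ndarray, calibrations: list[CalibrationParams]) -> np.ndarray:
    probs = np.empty_like(logits, dtype=float)
    for j, cal in enumerate(calibrations):
        probs[:, j] = apply_calibration(logits[:, j], cal)
    return probs


@dataclass
class SurgicalPlanResults:
    """Fitted planning stack: network, preprocessing, calibration, thresholds."""

    model: SurgicalPlanModel
    config: ModelConfig
    net: MultiTaskNet
    stats: PreprocessStats
    calibrations: list[CalibrationParams]
    thresholds: ThresholdSet
    training_log: dict
    loss_weights: LossWeights

    @property
    def n_params(self) -> int:
        return self.net.n_params

    def predict(self, df: pd.DataFrame) -> PredictedPlan:
        """Full prediction path: preprocess -> network -> calibration ->
        thresholds -> feasibility resolution."""
        feats = preprocess.derive_features(df)
        X = preprocess.transform(feats, self.stats)
        logits, doses = self.net.predict_logits(X)
        probs = _apply_per_label(logits, self.calibrations)
        return assemble_plan(probs, doses, self.thresholds)

    def predict_logits(self, df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        feats = preprocess.derive_features(df)
        X = preprocess.transform(feats, self.stats)
        return self.net.predict_logits(X)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self.config), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Surgical plan model (multi-task network)",
            "=" * 48,
            f"trunk: {cfg.input_width} -> " + " -> ".join(map(str, cfg.trunk_widths))
            + " -> 2 x 8 heads",
            f"parameters: {self.n_params}   dropout: {cfg.dropout}   "
            f"lr: {cfg.learning_rate:g}   weight decay: {cfg.weight_decay:g}",
            f"training rows: {len(self.model.features)}   "
            f"best epoch: {self.training_log['best_epoch']}"
            f" / stopped at {self.training_log['stopped_epoch']}"
            f"   best val loss: {self.training_log['best_val_loss']:.4f}",
            f"config hash: {self.config_hash()}   seed: {cfg.seed}",
            "",
            "label           pos.weight  temperature  beta(a,b,c)        threshold",
        ]
        for j, name in enumerate(LABELS):
            cal = self.calibrations[j]
            lines.append(
                f"{name:<15} {self.loss_weights.pos_weights[j]:>9.2f}"
                f"  {cal.temperature:>10.3f}"
                f"  ({cal.a:.2f},{cal.b:.2f},{cal.c:+.2f})"
                f"  {self.thresholds.thresholds[j]:>9.3f}"
            )
        return "\n".join(lines)

    def save(self, path) -> None:
        """Serialise the fitted stack to a documented JSON checkpoint."""
        payload = {
            "config": dataclasses.asdict(self.config),
            "config_hash": self.config_hash(),
            "params": {k: v.tolist() for k, v in self.net.params.items()},
            "running_mean": [m.tolist() for m in self.net.running_mean],
            "running_var": [v.tolist() for v in self.net.running_var],
            "dose_loc": self.net.dose_loc.tolist(),
            "dose_scale": self.net.dose_scale.tolist(),
            "stats": {
                "features": self.stats.features,
                "lower": self.stats.lower.tolist(),
                "upper": self.stats.upper.tolist(),
                "mean": self.stats.mean.tolist(),
                "sd": self.stats.sd.tolist(),
                "n_rows": self.stats.n_rows,
            },
            "calibrations": [dataclasses.asdict(c) for c in self.calibrations],
            "thresholds": self.thresholds.thresholds.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


DEFAULT_SEARCH_SPACE = {
    "trunk_width_1": (32, 160),
    "trunk_width_2": (16, 64),
    "dropout": (0.0, 0.5),
    "learning_rate": (1e-4, 1e-2),   # log-uniform
    "batch_size": [32, 64, 128],
}


def sample_config(space: dict, rng: np.random.Generator, base: ModelConfig) -> ModelConfig:
    w1 = int(rng.integers(space["trunk_width_1"][0], space["trunk_width_1"][1] + 1))
    w2 = int(rng.integers(space["trunk_width_2"][0], space["trunk_width_2"][1] + 1))
    drop = float(rng.uniform(*space["dropout"]))
    lo, hi = np.log(space["learning_rate"][0]), np.log(space["learning_rate"][1])
    lr = float(np.exp(rng.uniform(lo, hi)))
    bs = int(rng.choice(space["batch_size"]))
    return replace(
        base, trunk_widths=(w1, w2), dropout=drop, learning_rate=lr, batch_size=bs
    )


def random_search(
    space: dict,
    cohort: pd.DataFrame,
    k_inner: int = 3,
    budget: int = 10,
    seed: int = 0,
    base: ModelConfig | None = None,
    max_epochs: int | None = 150,
) -> tuple[ModelConfig, pd.DataFrame]:
    """Random-search hyper-parameter tuning on inner folds.

    Samples ``budget`` configurations uniformly from ``space`` (layer widths,
    dropout, log-uniform learning rate, batch size), scores each by the mean
    best validation loss over ``k_inner`` multilabel-stratified inner folds,
    and returns (best config, trial table).  Fully reproducible from
    ``seed``.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    for key in ("trunk_width_1", "trunk_width_2", "dropout", "learning_rate", "batch_size"):
        if key not in space or (hasattr(space[key], "__len__") and len(space[key]) == 0):
            raise ValueError(f"search space missing or empty entry: {key}")
    base = base or ModelConfig()
    if max_epochs is not None:
        base = replace(base, max_epochs=max_epochs)
    rng = np.random.default_rng(seed)
    labels = cohort[LABEL_COLUMNS].to_numpy()
    doses = cohort[DOSE_COLUMNS].to_numpy()
    feats = preprocess.derive_features(cohort)
    spec = multilabel_stratified_kfold(labels, k=k_inner, tolerance=5.0, seed=seed)

    trials = []
    best_cfg, best_score = None, np.inf
    for t in range(budget):
        cfg = sample_config(space, rng, base)
        cfg = replace(cfg, seed=int(rng.integers(0, 2 ** 31)))
        fold_losses = []
        for f in range(k_inner):
            val_rows = spec.fold_indices(f)
            train_rows = np.flatnonzero(spec.assignment != f)
            stats = preprocess.fit_winsor_standardise(feats.iloc[train_rows])
            X = preprocess.transform(feats, stats)
            net = MultiTaskNet(replace(cfg, input_width=X.shape[1]))
            train_log = net.train(
                X[train_rows], labels[train_rows], doses[train_rows],
                X[val_rows], labels[val_rows], doses[val_rows],
            )
            fold_losses.append(train_log["best_val_loss"])
        score = float(np.mean(fold_losses))
        trials.append(
            {
                "trial": t,
                "trunk_widths": cfg.trunk_widths,
                "dropout": cfg.dropout,
                "learning_rate": cfg.learning_rate,
                "batch_size": cfg.batch_size,
                "mean_val_loss": score,
            }
        )
        if score < best_score:
            best_score, best_cfg = score, cfg
        log.info("trial %d/%d: val loss %.4f", t + 1, budget, score)
    return best_cfg, pd.DataFrame(trials)


def config_to_yaml(config: ModelConfig, path) -> None:
    d = dataclasses.asdict(config)
    d["trunk_widths"] = list(config.trunk_widths)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def config_from_yaml(path) -> ModelConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "trunk_widths" in raw:
        raw["trunk_widths"] = tuple(raw["trunk_widths"])
    return ModelConfig(**raw)
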