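"""Quality screening, winsorisation and leakage-free standardisation.

All statistics (1st/99th-percentile winsor bounds, means, SDs) are computed
from training rows only and then applied unchanged to validation data, so
no information leaks across cross-validation folds.  Derived features
(axial-length mean and signed OD-OS difference, spherical-equivalent mean and
difference) are computed before standardisation.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import AGE_BOUNDS, AL_BOUNDS, DEVIATION_MAX

log = logging.getLogger(__name__)

#: model input features, fixed documented order
FEATURES = [
    "age",
    "deviating_eye",
    "deviation_angle",
    "al_mean",
    "al_diff",
    "se_mean",
    "se_diff",
    "bcva_od",
    "bcva_os",
    "equal_vision",
]

#: raw fields required to build the feature vector
REQUIRED_FIELDS = [
    "age",
    "deviating_eye",
    "deviation_angle",
    "axial_length_od",
    "axial_length_os",
    "se_od",
    "se_os",
    "bcva_od",
    "bcva_os",
    "equal_vision",
]


class MissingDataError(ValueError):
    """A required field is absent or non-finite (complete-case pipeline)."""


def check_bounds(record) -> list[str]:
    """Screen one record against the clinical admissibility bounds.

    Returns one human-readable flag per violated bound; an empty list means
    the record is admissible.  Bounds: age 2-65 y, axial length 18-32 mm
    (each eye), |deviation| <= 140 prism dioptres.
    """
    record = dict(record)
    for name in REQUIRED_FIELDS:
        value = record.get(name, None)
        if value is None or not np.isfinite(value):
            raise MissingDataError(
                f"field '{name}' is missing or non-numeric; the pipeline is "
                "complete-case and does not impute"
            )
    flags = []
    if not AGE_BOUNDS[0] <= record["age"] <= AGE_BOUNDS[1]:
        flags.append(f"age {record['age']:g} outside [{AGE_BOUNDS[0]:g}, {AGE_BOUNDS[1]:g}] y")
    for side in ("od", "os"):
        al = record[f"axial_length_{side}"]
        if not AL_BOUNDS[0] <= al <= AL_BOUNDS[1]:
            flags.append(
                f"axial_length_{side} {al:g} outside [{AL_BOUNDS[0]:g}, {AL_BOUNDS[1]:g}] mm"
            )
    if abs(record["deviation_angle"]) > DEVIATION_MAX:
        flags.append(
            f"deviation_angle {record['deviation_angle']:g} exceeds +/-{DEVIATION_MAX:g} prism dioptres"
        )
    return flags


def derive_features(df: pd.DataFrame) -> pd.DataFrame:
    """Raw records -> unstandardised feature table in :data:`FEATURES` order."""
    for name in REQUIRED_FIELDS:
        if name not in df.columns:
            raise MissingDataError(f"column '{name}' absent from input table")
        if not np.isfinite(df[name].to_numpy(dtype=float)).all():
            raise MissingDataError(f"column '{name}' contains missing values")
    out = pd.DataFrame(index=df.index)
    out["age"] = df["age"]
    out["deviating_eye"] = df["deviating_eye"]
    out["deviation_angle"] = df["deviation_angle"]
    out["al_mean"] = (df["axial_length_od"] + df["axial_length_os"]) / 2.0
    out["al_diff"] = df["axial_length_od"] - df["axial_length_os"]  # signed OD - OS
    out["se_mean"] = (df["se_od"] + df["se_os"]) / 2.0
    out["se_diff"] = df["se_od"] - df["se_os"]
    out["bcva_od"] = df["bcva_od"]
    out["bcva_os"] = df["bcva_os"]
    out["equal_vision"] = df["equal_vision"]
    return out[FEATURES]


@dataclass
class PreprocessStats:
    """Winsor bounds and standardisation moments fitted on a training fold."""

    features: list[str]
    lower: np.ndarray  # 1st-percentile bound per feature
    upper: np.ndarray  # 99th-percentile bound per feature
    mean: np.ndarray   # mean of the winsorised training column
    sd: np.ndarray     # SD of the winsorised training column (1.0 fallback)
    n_rows: int = 0    # provenance: number of training rows used

    def to_json(self, path) -> None:
        payload = {
            "features": self.features,
            "lower": self.lower.tolist(),
            "upper": self.upper.tolist(),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "n_rows": self.n_rows,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PreprocessStats":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            features=payload["features"],
            lower=np.asarray(payload["lower"]),
            upper=np.asarray(payload["upper"]),
            mean=np.asarray(payload["mean"]),
            sd=np.asarray(payload["sd"]),
            n_rows=payload.get("n_rows", 0),
        )


def fit_winsor_standardise(train: pd.DataFrame) -> PreprocessStats:
    """Fit winsor bounds (empirical 1st/99th percentiles, linear interpolation
    between order statistics) and post-clipping mean/SD on training rows.

    Constant columns get SD 1 with a logged warning, so their standardised
    values become 0.
    """
    if len(train) < 2:
        raise ValueError("need at least 2 training rows to fit preprocessing stats")
    X = train.to_numpy(dtype=float)
    lower = np.percentile(X, 1, axis=0, method="linear")
    upper = np.percentile(X, 99, axis=0, method="linear")
    clipped = np.clip(X, lower, upper)
    mean = clipped.mean(axis=0)
    sd = clipped.std(axis=0, ddof=0)
    constant = sd == 0.0
    if constant.any():
        names = [c for c, flag in zip(train.columns, constant) if flag]
        log.warning("constant feature column(s) %s: SD fallback to 1", names)
        sd = np.where(constant, 1.0, sd)
    return PreprocessStats(
        features=list(train.columns),
        lower=lower,
        upper=upper,
        mean=mean,
        sd=sd,
        n_rows=len(train),
    )


def transform(features: pd.DataFrame, stats: PreprocessStats) -> np.ndarray:
    """Clip to the fitted winsor bounds then z-score with the fitted moments."""
    X = features[stats.features].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise MissingDataError("non-finite value in feature table")
    clipped = np.clip(X, stats.lower, stats.upper)
    return (clipped - stats.mean) / stats.sd
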