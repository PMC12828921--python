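"""Synthetic cohort simulator for horizontal strabismus surgery planning.

Generates patient records (the 14 routine pre-operative predictors) together
with expert-style surgical plans: an 8-label muscle-procedure vector and the
corresponding recession/resection doses in mm.  The generator is calibrated to
the published baseline statistics of a 634-patient surgical cohort (exotropia
fraction 53.2%, deviation 28 +/- 10 prism dioptres overall and 31 +/- 11 in
exotropes, axial length 24.0 +/- 1.2 mm, median age 15 y) and to the classical
"1 mm of surgery corrects about 2 prism dioptres" nomogram, under which
recession doses cluster in the 6-7 mm range.

Label order (fixed everywhere in the package)::

    R-MR-recess, R-MR-resect, R-LR-recess, R-LR-resect,
    L-MR-recess, L-MR-resect, L-LR-recess, L-LR-resect

where R/L = right (OD) / left (OS) eye, MR/LR = medial/lateral rectus.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

LABELS = [
    "R_MR_recess",
    "R_MR_resect",
    "R_LR_recess",
    "R_LR_resect",
    "L_MR_recess",
    "L_MR_resect",
    "L_LR_recess",
    "L_LR_resect",
]

LABEL_COLUMNS = [f"label_{name}" for name in LABELS]
DOSE_COLUMNS = [f"dose_{name}" for name in LABELS]

#: muscle pairs that may never be simultaneously recessed and resected
EXCLUSIVE_PAIRS = [(0, 1), (2, 3), (4, 5), (6, 7)]

#: raw predictor columns written to the cohort CSV (the 14-predictor table:
#: 10 measured values/flags plus the 4 derived axial-length / refraction terms)
PREDICTOR_COLUMNS = [
    "age",
    "deviating_eye",
    "deviation_angle",
    "axial_length_od",
    "axial_length_os",
    "al_mean",
    "al_diff",
    "se_od",
    "se_os",
    "se_mean",
    "se_diff",
    "bcva_od",
    "bcva_os",
    "equal_vision",
]

AGE_BOUNDS = (2.0, 65.0)
AL_BOUNDS = (18.0, 32.0)
DEVIATION_MAX = 140.0


class ConfigurationError(ValueError):
    """A generator configuration field is outside its admissible range."""


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic-cohort generative model.

    Deviation angles are signed: positive = exotropia, negative = esotropia.
    ``|deviation|`` is drawn from a per-type normal (truncated to
    ``[deviation_min, 140]`` by rejection).  Surgical plans follow a
    deterministic expert rule (see :func:`assign_plan`); label noise is
    injected afterwards by independent Bernoulli flips.
    """

    n_patients: int = 634
    seed: int = 0
    p_exotropia: float = 0.532
    # age ~ lognormal; median exp(mu) = 15 y, sigma chosen to match IQR 11-23
    age_log_mu: float = math.log(15.0)
    age_log_sigma: float = 0.547
    # |deviation| per strabismus type, prism dioptres
    deviation_exo_mean: float = 31.0
    deviation_exo_sd: float = 11.0
    deviation_eso_mean: float = 24.0
    deviation_eso_sd: float = 9.0
    deviation_min: float = 5.0
    # axial length (per-patient mean, mm) and inter-ocular difference
    axial_length_mean: float = 24.0
    axial_length_sd: float = 1.2
    al_diff_sd: float = 0.6
    # spherical equivalent (dioptres)
    se_mean: float = -1.3
    se_sd: float = 2.4
    se_diff_sd: float = 1.2
    # BCVA logMAR mixture: point mass at 0.00 else half-normal(sigma)
    bcva_p_zero: float = 0.55
    bcva_sigma: float = 0.15
    equal_vision_margin: float = 0.1
    # surgical rule: prism dioptres corrected per mm of surgery on one muscle
    # when the correction is shared (surgical tables give ~2.1-2.7 for
    # two-muscle procedures; the classic single-muscle approximation is ~2)
    nomogram_slope: float = 2.15
    unilateral_threshold: float = 10.0  # |dev| <= thr -> single-muscle surgery
    dose_noise_sd: float = 0.3  # mm
    label_flip_rate: float = 0.02
    min_label_prevalence: float = 0.05

    def validate(self) -> None:
        probs = {
            "p_exotropia": self.p_exotropia,
            "bcva_p_zero": self.bcva_p_zero,
            "label_flip_rate": self.label_flip_rate,
            "min_label_prevalence": self.min_label_prevalence,
        }
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        positive = {
            "age_log_sigma": self.age_log_sigma,
            "deviation_exo_sd": self.deviation_exo_sd,
            "deviation_eso_sd": self.deviation_eso_sd,
            "axial_length_sd": self.axial_length_sd,
            "al_diff_sd": self.al_diff_sd,
            "se_sd": self.se_sd,
            "se_diff_sd": self.se_diff_sd,
            "bcva_sigma": self.bcva_sigma,
            "nomogram_slope": self.nomogram_slope,
        }
        for name, value in positive.items():
            if not value > 0.0:
                raise ConfigurationError(f"{name} must be > 0, got {value}")
        if self.dose_noise_sd < 0.0:
            raise ConfigurationError(
                f"dose_noise_sd must be >= 0, got {self.dose_noise_sd}"
            )
        if self.n_patients < 0:
            raise ConfigurationError(
                f"n_patients must be >= 0, got {self.n_patients}"
            )
        if not self.unilateral_threshold > 0:
            raise ConfigurationError(
                f"unilateral_threshold must be > 0, got {self.unilateral_threshold}"
            )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _truncated_normal(rng: np.random.Generator, mean, sd, lo, hi, size) -> np.ndarray:
    """Rejection-sample N(mean, sd) restricted to [lo, hi] (no boundary spikes)."""
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def dose_from_deviation(
    deviation: float,
    n_muscles_sharing: int,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> float:
    """Surgical dose (mm) for one muscle from the shared-correction nomogram.

    dose = clip(|deviation| / (slope * n_muscles) + N(0, dose_noise_sd), 0.5, 10)
    """
    if n_muscles_sharing < 1:
        raise ValueError(
            f"n_muscles_sharing must be >= 1, got {n_muscles_sharing}"
        )
    if deviation == 0:
        raise ValueError("deviation must be nonzero for an operated muscle")
    raw = abs(deviation) / (config.nomogram_slope * n_muscles_sharing)
    if config.dose_noise_sd > 0:
        raw += rng.normal(0.0, config.dose_noise_sd)
    return float(np.clip(raw, 0.5, 10.0))


def _rule_labels(record: dict, config: GeneratorConfig) -> tuple[list[int], int]:
    """Deterministic expert rule: which labels are active, and how many
    muscles share the correction.

    Exotropia recesses the lateral rectus (resects the medial rectus);
    esotropia the converse.  Small deviations (<= unilateral_threshold) get
    a single recession on the deviating eye.  Otherwise two muscles share
    the correction: symmetric bilateral recession when vision is equal,
    recess-resect on the deviating (amblyopic) eye when it is not.  Very
    large angles saturate at the 10 mm per-muscle ceiling.
    """
    exo = record["deviation_angle"] > 0
    eye = int(record["deviating_eye"])  # 0 = OD (right), 1 = OS (left)
    a = abs(record["deviation_angle"])

    def idx(eye_code: int, muscle: str, proc: str) -> int:
        base = 0 if eye_code == 0 else 4
        offset = {"MR_recess": 0, "MR_resect": 1, "LR_recess": 2, "LR_resect": 3}
        return base + offset[f"{muscle}_{proc}"]

    recess_muscle = "LR" if exo else "MR"
    resect_muscle = "MR" if exo else "LR"

    active: list[int]
    if a <= config.unilateral_threshold:
        active = [idx(eye, recess_muscle, "recess")]
        n_share = 1
    elif record["equal_vision"] == 1:
        active = [idx(0, recess_muscle, "recess"), idx(1, recess_muscle, "recess")]
        n_share = 2
    else:
        active = [idx(eye, recess_muscle, "recess"), idx(eye, resect_muscle, "resect")]
        n_share = 2
    return active, n_share


def assign_plan(
    record: dict, config: GeneratorConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Assign an expert-style surgical plan to one patient record.

    Returns ``(labels, doses)``: 8 binary flags and 8 doses in mm.  The
    pre-noise plan always satisfies dose > 0 <=> label = 1 and never recesses
    and resects the same muscle.  Each label is then independently flipped
    with ``label_flip_rate`` (recording noise) and doses are re-zeroed
    wherever the final label is 0; flipped-on labels keep dose 0.
    """
    active, n_share = _rule_labels(record, config)
    labels = np.zeros(8, dtype=int)
    doses = np.zeros(8)
    for j in active:
        labels[j] = 1
        doses[j] = dose_from_deviation(
            record["deviation_angle"], n_share, config, rng
        )
    if config.label_flip_rate > 0:
        flips = rng.random(8) < config.label_flip_rate
        labels = np.where(flips, 1 - labels, labels)
        doses = np.where(labels == 1, doses, 0.0)
    return labels, doses


def rule_label_probabilities(record: dict, config: GeneratorConfig) -> np.ndarray:
    """Analytic P(label=1) for one record under the rule + flip noise.

    Independent oracle used to verify Monte-Carlo marginals: the rule is
    deterministic, so the only randomness is the Bernoulli flip.
    """
    active, _ = _rule_labels(record, config)
    base = np.zeros(8)
    base[active] = 1.0
    f = config.label_flip_rate
    return base * (1 - f) + (1 - base) * f


def simulate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a synthetic cohort as a DataFrame (one row per patient).

    Columns: ``patient_id``, the 14 predictor columns
    (:data:`PREDICTOR_COLUMNS`), 8 ``label_*`` and 8 ``dose_*`` columns.
    Identical config (including seed) yields a bit-identical cohort.  The
    cohort is redrawn (deterministic sub-seeds) until every label reaches
    ``min_label_prevalence``.
    """
    config.validate()
    if config.n_patients == 0:
        cols = (
            ["patient_id"] + PREDICTOR_COLUMNS + LABEL_COLUMNS + DOSE_COLUMNS
        )
        return pd.DataFrame(columns=cols)

    ss = np.random.SeedSequence(config.seed)
    for attempt, child in enumerate(ss.spawn(20)):
        rng = np.random.default_rng(child)
        df = _draw_cohort(config, rng)
        prev = df[LABEL_COLUMNS].mean().to_numpy()
        if config.n_patients < 50 or (prev >= config.min_label_prevalence).all():
            return df
    raise RuntimeError(
        "could not reach min_label_prevalence for all labels in 20 attempts; "
        f"last prevalences: {prev.round(3).tolist()}"
    )


def _draw_cohort(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_patients
    age = _truncated_normal(
        rng,
        0.0,
        1.0,
        (math.log(AGE_BOUNDS[0]) - config.age_log_mu) / config.age_log_sigma,
        (math.log(AGE_BOUNDS[1]) - config.age_log_mu) / config.age_log_sigma,
        n,
    )
    age = np.exp(config.age_log_mu + config.age_log_sigma * age)

    exo = rng.random(n) < config.p_exotropia
    dev = np.empty(n)
    n_exo = int(exo.sum())
    dev[exo] = _truncated_normal(
        rng,
        config.deviation_exo_mean,
        config.deviation_exo_sd,
        config.deviation_min,
        DEVIATION_MAX,
        n_exo,
    )
    dev[~exo] = -_truncated_normal(
        rng,
        config.deviation_eso_mean,
        config.deviation_eso_sd,
        config.deviation_min,
        DEVIATION_MAX,
        n - n_exo,
    )

    deviating_eye = (rng.random(n) < 0.5).astype(int)

    al_mean = _truncated_normal(
        rng, config.axial_length_mean, config.axial_length_sd,
        AL_BOUNDS[0] + 1.0, AL_BOUNDS[1] - 1.0, n,
    )
    al_diff = _truncated_normal(rng, 0.0, config.al_diff_sd, -2.0, 2.0, n)
    al_od = al_mean + al_diff / 2.0
    al_os = al_mean - al_diff / 2.0

    se_mean = rng.normal(config.se_mean, config.se_sd, n)
    se_diff = rng.normal(0.0, config.se_diff_sd, n)
    se_od = se_mean + se_diff / 2.0
    se_os = se_mean - se_diff / 2.0

    def bcva(size):
        zero = rng.random(size) < config.bcva_p_zero
        vals = np.abs(rng.normal(0.0, config.bcva_sigma, size))
        return np.where(zero, 0.0, vals)

    bcva_od = bcva(n)
    bcva_os = bcva(n)
    equal_vision = (
        np.abs(bcva_od - bcva_os) <= config.equal_vision_margin
    ).astype(int)

    records = pd.DataFrame(
        {
            "patient_id": np.arange(n),
            "age": age,
            "deviating_eye": deviating_eye,
            "deviation_angle": dev,
            "axial_length_od": al_od,
            "axial_length_os": al_os,
            "al_mean": (al_od + al_os) / 2.0,
            "al_diff": al_od - al_os,
            "se_od": se_od,
            "se_os": se_os,
            "se_mean": (se_od + se_os) / 2.0,
            "se_diff": se_od - se_os,
            "bcva_od": bcva_od,
            "bcva_os": bcva_os,
            "equal_vision": equal_vision,
        }
    )

    labels = np.zeros((n, 8), dtype=int)
    doses = np.zeros((n, 8))
    for i in range(n):
        labels[i], doses[i] = assign_plan(records.iloc[i].to_dict(), config, rng)
    for j, col in enumerate(LABEL_COLUMNS):
        records[col] = labels[:, j]
    for j, col in enumerate(DOSE_COLUMNS):
        records[col] = doses[:, j]
    return records


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    """Write a cohort to CSV with the documented column order."""
    df.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [
        c
        for c in PREDICTOR_COLUMNS + LABEL_COLUMNS + DOSE_COLUMNS
        if c not in df.columns
    ]
    if missing:
        raise ValueError(f"cohort CSV is missing columns: {missing}")
    return df
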