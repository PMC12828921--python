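import numpy as np
import pandas as pd
import pytest

from strabplan import GeneratorConfig, ModelConfig, SurgicalPlanModel, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """The default study-sized cohort (n=634, fixed seed)."""
    return simulate_cohort(GeneratorConfig(n_patients=634, seed=0))


@pytest.fixture(scope="session")
def big_cohort() -> pd.DataFrame:
    """A large cohort for Monte-Carlo convergence checks."""
    return simulate_cohort(GeneratorConfig(n_patients=10_000, seed=1234))


@pytest.fixture(scope="session")
def noise_free_recovery():
    """Held-out exact-match and operated-dose MAE when the simulator runs
    with zero label flips and zero dose noise (the plan is then a
    deterministic function of the features)."""
    from strabplan.evaluation import classification_metrics, regression_metrics
    from strabplan.simulate import DOSE_COLUMNS, LABEL_COLUMNS

    gen = GeneratorConfig(
        n_patients=1500, seed=13, label_flip_rate=0.0, dose_noise_sd=0.0
    )
    df = simulate_cohort(gen)
    train, val = df.iloc[:1200], df.iloc[1200:]
    res = SurgicalPlanModel.from_dataframe(train, config=ModelConfig()).fit(seed=3)
    plan = res.predict(val)
    labels = val[LABEL_COLUMNS].to_numpy()
    doses = val[DOSE_COLUMNS].to_numpy()
    cm = classification_metrics(plan.probabilities, plan.decisions, labels)
    op = doses > 0
    rm = regression_metrics(plan.doses[op], doses[op])
    return cm["exact_match"], rm["mae"]


@pytest.fixture(scope="session")
def fitted_split(default_cohort):
    """One fitted planning stack and its held-out evaluation frame.

    Trains on the first 507 patients; the last 127 are never seen.
    Session-scoped because training takes a few seconds.
    """
    train = default_cohort.iloc[:507]
    val = default_cohort.iloc[507:].reset_index(drop=True)
    model = SurgicalPlanModel.from_dataframe(train, config=ModelConfig())
    results = model.fit(seed=7)
    return results, val
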