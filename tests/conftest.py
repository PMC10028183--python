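import numpy as np
import pytest

from cambnet.synthetic import PhantomSpec, generate_cohort
from cambnet.training import TrainConfig, train_on_cohort

#: single seed driving the session-scoped fixtures
SEED = 0


@pytest.fixture(scope="session")
def cohort200():
    """200-case default-spec phantom cohort (the learnability test bed)."""
    return generate_cohort(n_cases=200, seed=SEED)


@pytest.fixture(scope="session")
def trained_model(cohort200):
    """CAMBNet trained 30 epochs on the 200-case cohort, patient-wise split.

    Session-scoped: the classification and explainability checks share it.
    """
    cases, _ = cohort200
    cfg = TrainConfig(max_epochs=30, seed=SEED)
    model, history, plan, patches = train_on_cohort(cases, cfg)
    return {"model": model, "history": history, "plan": plan,
            "patches": patches, "cases": cases, "config": cfg}


@pytest.fixture(scope="session")
def small_cohort():
    """24 cases on a smaller canvas; enough for split/training mechanics."""
    spec = PhantomSpec(image_side=128)
    return generate_cohort(n_cases=24, spec=spec, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
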