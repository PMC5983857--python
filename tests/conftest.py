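import numpy as np
import pytest

from targetscreen.pipeline import labeled_targets, prepare_dataset
from targetscreen.synthetic import (
    ClassEffect,
    ClassSpec,
    DatasetSpec,
    PlantedEffect,
    SimulationConfig,
    simulate_study,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def confound_study():
    """60/20 labeled sample with one genuine effect and one class-driven one.

    f001 carries a true outcome effect (delta = 2 pooled SDs); f002 is
    shifted for members of a success-enriched class (38/40 successes) and
    has no direct outcome dependence.
    """
    cfg = SimulationConfig(
        seed=11,
        n_success=60,
        n_fail=20,
        n_unlabeled=0,
        datasets=[DatasetSpec("expr", n_genes=80, n_features=12)],
        planted_effects=[
            PlantedEffect("expr", "named-feature", feature="f001", delta=2.0, sign=+1)
        ],
        class_structure=[ClassSpec("GPCR-like", 40, 0.95)],
        class_effects=[ClassEffect("expr", "f002", "GPCR-like", shift=4.0)],
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def confound_reduced(confound_study):
    labels = confound_study.outcome_labels
    return prepare_dataset(confound_study.datasets[0], labeled_targets(labels))


@pytest.fixture(scope="session")
def paper_scale_study():
    """259 successes / 72 failures with the historical class composition."""
    cfg = SimulationConfig(
        seed=7,
        n_success=259,
        n_fail=72,
        n_unlabeled=50,
        datasets=[DatasetSpec("expr", n_genes=381, n_features=10)],
        planted_effects=[],
        class_structure=[
            ClassSpec("GPCR-like", 70, 62 / 70),
            ClassSpec("integrin-like", 3, 0.0),
        ],
    )
    return simulate_study(cfg)
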