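import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from rankset import (
    SetSpec,
    SimulationConfig,
    filter_low_expression,
    log_cpm,
    moderated_two_group_test,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def null_experiment():
    """One simulated experiment with no planted effects."""
    config = SimulationConfig(n_genes=2000, seed=11)
    return simulate_experiment(config)


@pytest.fixture(scope="session")
def planted_experiment():
    """Glucose-up / drug-reversed planted sets among null sets."""
    config = SimulationConfig(
        n_genes=4000,
        set_specs=(
            SetSpec(50, 2, delta_glucose=2.0, delta_vpa=-2.0),
            SetSpec(40, 5, delta_glucose=0.0, delta_vpa=0.0),
        ),
        seed=5,
    )
    return simulate_experiment(config)


@pytest.fixture(scope="session")
def planted_de_pair(planted_experiment):
    """DE tables for both contrasts of the planted experiment."""
    cm, _, _ = planted_experiment
    cm = filter_low_expression(cm)
    logexpr = log_cpm(cm)
    de1 = moderated_two_group_test(logexpr, cm.design, "LG", "HG")
    de2 = moderated_two_group_test(logexpr, cm.design, "HG", "HGV")
    return de1, de2


def random_de_table(rng: np.random.Generator, n: int, prefix: str = "G") -> pd.DataFrame:
    """A syntactically valid DE table with random contents."""
    from rankset.diffexpr import bh_adjust

    p = rng.uniform(1e-12, 1.0, size=n)
    return pd.DataFrame(
        {
            "gene_id": [f"{prefix}{i:05d}" for i in range(n)],
            "log2fc": rng.normal(0, 2, size=n),
            "p": p,
            "fdr": bh_adjust(p),
            "ave_expr": rng.normal(5, 2, size=n),
        }
    )
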