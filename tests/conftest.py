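import warnings

import numpy as np
import pytest
from hypothesis import settings

import qpcrde as q

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(20130618)


def make_recovery_config(seed: int = 11) -> q.SimulationConfig:
    """Study-sized design with one null and two planted fold changes.

    40 animals, 5 tissues, 2 reference + 2 target genes; target T2 carries
    a 2-fold excess in liver and an 8-fold excess in backfat relative to
    hypothalamus, target T1 is flat everywhere (null).
    """
    genes = (
        q.GeneSim("R1", "reference", 0.93),
        q.GeneSim("R2", "reference", 0.80),
        q.GeneSim("T1", "target", 0.90),
        q.GeneSim("T2", "target", 0.90, levels={"liver": 1.0, "backfat": 3.0}),
    )
    return q.SimulationConfig(seed=seed, genes=genes)


RECOVERY_CONTRASTS = (
    q.ContrastSpec("T1", "liver", "hypothalamus", ("R1", "R2")),
    q.ContrastSpec("T2", "liver", "hypothalamus", ("R1", "R2")),
    q.ContrastSpec("T2", "backfat", "hypothalamus", ("R1", "R2")),
)


@pytest.fixture(scope="session")
def recovery_summary():
    """500-replicate parameter-recovery run at the study design size.

    Session-scoped: several tests read different columns of the same
    summary (rejection rate, coverage, bias) without re-simulating.
    """
    cfg = make_recovery_config()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return q.recovery_experiment(
            cfg, list(RECOVERY_CONTRASTS), n_reps=500, seed=99
        )


@pytest.fixture
def mimic_dataset():
    cfg = q.paper_mimic_config(seed=7)
    ds, truth = q.simulate_cp_dataset(cfg)
    return ds, truth
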