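import numpy as np
import pytest

import hipecpk as hp
from hipecpk.recovery import catheter_recoveries, correct_observations
from hipecpk.simulate import TISSUE_LAYOUT, default_truth


def subset_config(tissues, **kwargs):
    """Generator config restricted to a few tissue compartments."""
    truth = default_truth()
    return hp.GeneratorConfig(
        truth={t: truth[t] for t in tissues},
        recovery={t: (TISSUE_LAYOUT[t][2], TISSUE_LAYOUT[t][3]) for t in tissues},
        **kwargs,
    )


@pytest.fixture(scope="session")
def noise_free_experiment():
    """Deterministic curves: no residual noise, no animal variability, no dropout."""
    cfg = subset_config(
        ["liver_1", "peritoneum_1"],
        n_animals=3,
        residual_log_sd=0.0,
        bsv_log_k_in=0.0,
        bsv_log_k_e=0.0,
        catheter_failure_prob=0.0,
    )
    return cfg, hp.generate_experiment(cfg, seed=11)


@pytest.fixture(scope="session")
def corrected_noise_free(noise_free_experiment):
    cfg, exp = noise_free_experiment
    rec = catheter_recoveries(exp.calibration)
    return cfg, correct_observations(exp.observations, rec, lloq=cfg.lloq)


@pytest.fixture(scope="session")
def default_experiment():
    """Full default study conditions (8 animals, 9 compartments, dropout)."""
    cfg = hp.GeneratorConfig()
    return cfg, hp.generate_experiment(cfg, seed=7)


def random_pk_params(rng: np.random.Generator) -> hp.PKParams:
    """Parameter draws spanning the physiologic range and beyond."""
    return hp.PKParams(
        k_in=float(rng.uniform(0.001, 0.2)),
        t_in=float(rng.uniform(20.0, 300.0)),
        k_e=float(rng.uniform(0.005, 0.15)),
    )
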