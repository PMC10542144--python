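import numpy as np
import pytest

import cheascope as cs
from cheascope.pipeline import analyze_cohort
from cheascope.stats import composition_summary


@pytest.fixture(scope="session")
def default_config():
    return cs.default_generator_config()


@pytest.fixture(scope="session")
def models():
    return cs.default_models()


def zero_perturbation(cfg):
    """Default config with every sequence perturbation switched off."""
    return cfg.replace(
        degrade_prob=0.0, split_prob=0.0, his_loss_prob=0.0, dim_extended_prob=0.0
    )


@pytest.fixture(scope="session")
def small_clean_cohort(default_config):
    """Zero-perturbation cohort: scanner output must equal ground truth."""
    cfg = zero_perturbation(default_config)
    return cs.generate_cohort(cfg, 400, seed=11)


@pytest.fixture(scope="session")
def big_cohort(default_config):
    """The survey-scale synthetic cohort (n = 20,000) used for
    marginal-recovery checks, with the full analysis pipeline applied."""
    cohort = cs.generate_cohort(default_config, 20_000, seed=101)
    classes = {r.protein_id: r.class_label for r in cohort.truth}
    hits, records = analyze_cohort(
        cohort.sequences, classes, cs.ScanConfig(), cs.BuilderConfig()
    )
    return cohort, records


@pytest.fixture(scope="session")
def big_summary(big_cohort):
    _, records = big_cohort
    chea = [r for r in records if r.flags["is_cheA"]]
    return chea, composition_summary(chea)


def binom_band(p: float, n: int, k: float = 4.0) -> float:
    """k binomial standard errors, in percentage points."""
    return 100.0 * k * np.sqrt(p * (1 - p) / n)
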