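import pytest

from sltplan import SimConfig, default_catalogue, generate_corpus


@pytest.fixture(scope="session")
def catalogue():
    return default_catalogue()


@pytest.fixture(scope="session")
def small_cohort(catalogue):
    """A 30-case low-noise cohort shared by retrieval/clustering tests."""
    cfg = SimConfig(
        n_cases=30,
        condition_mix={
            "cerebral palsy": 8,
            "down syndrome": 7,
            "intellectual disability": 5,
            "autistic disorder": 4,
            "fetal alcohol syndrome": 3,
            "mixed language disorder": 3,
        },
        seed=11,
    )
    cases, truth = generate_corpus(cfg, catalogue)
    return cfg, cases, truth


@pytest.fixture(scope="session")
def clean_cohort(catalogue):
    """A noise-free cohort: identical profiles and plans within a condition."""
    cfg = SimConfig(
        n_cases=24,
        condition_mix={
            "cerebral palsy": 6,
            "down syndrome": 6,
            "intellectual disability": 4,
            "autistic disorder": 4,
            "fetal alcohol syndrome": 2,
            "mixed language disorder": 2,
        },
        eval_flip_prob=0.0,
        med_flip_prob=0.0,
        plan_flip_prob=0.0,
        seed=5,
    )
    cases, truth = generate_corpus(cfg, catalogue)
    return cfg, cases, truth
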