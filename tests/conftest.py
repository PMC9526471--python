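import pytest

from mtcseq import classify, diffexp, feature_sets
from mtcseq.pipeline import RunConfig, run_pipeline
from mtcseq.simulate import (SimConfig, gene_params, simulate_cohorts,
                             simulate_controls)


def small_sim(seed: int = 3, **overrides) -> SimConfig:
    """A scaled-down simulation config for fast unit tests."""
    base = dict(
        n_genes=400,
        n_signature=40,
        n_cassette=34,
        n_cassette_core=5,
        cohort_sizes={"train_fnab": (8, 40), "tissue": (6, 12),
                      "valid_fnab": (6, 20)},
        n_control_groups=4,
        n_control_replicates=2,
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def default_config():
    return SimConfig(seed=7)


@pytest.fixture(scope="session")
def cohorts(default_config):
    return simulate_cohorts(default_config)


@pytest.fixture(scope="session")
def controls(default_config):
    return simulate_controls(default_config)


@pytest.fixture(scope="session")
def truth(default_config):
    return gene_params(default_config)


@pytest.fixture(scope="session")
def detable(cohorts):
    both = cohorts.select_samples(
        cohorts.sample_meta["cohort"].isin(["train_fnab", "tissue"]).to_numpy())
    return diffexp.dual_context_table(both)


@pytest.fixture(scope="session")
def candidate_sets(detable, cohorts, truth):
    return feature_sets.build_all_sets(detable, cohorts, truth.cassette_genes)


@pytest.fixture(scope="session")
def svm_set2(cohorts, candidate_sets):
    """Linear SVM trained on candidate set 2 over the default training FNABs."""
    train = cohorts.cohort("train_fnab")
    fset = candidate_sets[1]
    return classify.train(train, fset.genes, "svm", feature_set_id=2)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """A complete pipeline run at reduced scale, for artifact-level tests."""
    out = tmp_path_factory.mktemp("small_pipeline") / "run"
    cfg = RunConfig(seed=5, outdir=str(out), sim=small_sim(seed=5),
                    cv_folds=4, cv_repeats=2)
    return cfg, run_pipeline(cfg)


@pytest.fixture(scope="session")
def full_run(tmp_path_factory):
    """The default-scale end-to-end run (paper cohort sizes, 16 settings,
    10x5-fold CV); shared across the validation-level tests."""
    out = tmp_path_factory.mktemp("full_pipeline") / "run"
    cfg = RunConfig(seed=11, outdir=str(out))
    cfg.sim.seed = 11
    return cfg, run_pipeline(cfg)
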