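import numpy as np
import pytest

from mdcore import (
    BetaTable,
    core_classification,
    extended_md_pipeline,
    generate_task_betas,
    make_default_config,
)


@pytest.fixture(scope="session")
def default_config():
    return make_default_config(seed=0)


@pytest.fixture(scope="session")
def default_betas(default_config):
    return generate_task_betas(default_config)


@pytest.fixture(scope="session")
def default_partition(default_config, default_betas):
    """(averaged table, per-contrast stats, extended conjunction, core split)."""
    avg, stats, extended = extended_md_pipeline(default_betas)
    core = core_classification(avg, extended.extended_set)
    return avg, stats, extended, core


def random_beta_table(rng, n_subjects=6, n_areas=5, n_contrasts=3, hemispheres=False):
    n_cols = 2 * n_areas if hemispheres else n_areas
    beta = rng.normal(size=(n_subjects, n_cols, n_contrasts))
    names = tuple(f"A{i}" for i in range(n_areas))
    return BetaTable(
        beta=beta,
        subject_ids=tuple(f"s{i}" for i in range(n_subjects)),
        area_ids=names * 2 if hemispheres else names,
        contrast_ids=tuple(f"c{i}" for i in range(n_contrasts)),
        hemispheres=("L",) * n_areas + ("R",) * n_areas if hemispheres else None,
    )
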