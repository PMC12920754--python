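import numpy as np
import pytest

from nodalcut import (
    build_region_table,
    generate_cohort,
    join_regions,
    mapping_endometrial_like,
)


@pytest.fixture(scope="session")
def endo_cohort():
    """Endometrial-like synthetic cohort at study scale (99 regions), seed 17."""
    cfg = mapping_endometrial_like(seed=17)
    tables, truth = generate_cohort(cfg)
    return cfg, tables, truth


@pytest.fixture(scope="session")
def region_frame(endo_cohort):
    _, tables, _ = endo_cohort
    return build_region_table(join_regions(tables))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)
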