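import numpy as np
import pytest

import hinnlab as hl


@pytest.fixture(scope="session")
def default_cohort():
    """Default study-size cohort (n=500, 200/300/100/30) with planted cascades."""
    return hl.simulate_cohort(hl.SimulationParams(seed=1))


@pytest.fixture(scope="session")
def selection(default_cohort):
    cohort, _ = default_cohort
    return hl.select_features(cohort, hl.QCThresholds())


@pytest.fixture(scope="session")
def masks(default_cohort, selection):
    cohort, _ = default_cohort
    return hl.build_masks(selection.relation_map, cohort.snp_annotations,
                          cohort.cpg_annotations, cohort.gene_annotations)


@pytest.fixture(scope="session")
def model_inputs(default_cohort, masks):
    cohort, _ = default_cohort
    return hl.prepare_model_inputs(cohort, masks, hl.ArchitectureConfig())


def tiny_maskset(rng=None):
    """A small deterministic MaskSet for unit tests (3 SNP, 4 CpG, 3 probe, 2 term)."""
    m1 = np.array([[1, 1, 0, 0], [0, 1, 1, 0], [0, 0, 1, 1]], float)
    m2 = np.array([[1, 0, 0], [1, 1, 0], [0, 1, 1], [0, 0, 1]], float)
    m3 = np.array([[1, 0], [1, 1], [0, 1]], float)
    return hl.MaskSet([f"s{i}" for i in range(3)], [f"c{i}" for i in range(4)],
                      [f"p{i}" for i in range(3)], [f"t{i}" for i in range(2)],
                      m1, m2, m3)
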