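import numpy as np
import pytest

from adcscreen.synthetic import CohortConfig, PanelConfig, generate_breast_cohort, \
    generate_cell_line_panel


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def small_cohort():
    """A small, well-separated four-class cohort with clean seed labels."""
    cfg = CohortConfig(n_per_class=20, n_genes=120, noise_sd=0.5,
                       mislabel_frac=0.0, missing_receptor_frac=0.0, seed=11)
    return generate_breast_cohort(cfg)


@pytest.fixture(scope="session")
def small_panel():
    cfg = PanelConfig(n_lines_per_class={"epithelial": 4, "mesenchymal": 4,
                                         "mixed": 3, "melanoma": 3, "leukemia": 3},
                      n_replicates=3, cluster_genes_per_class=10, n_genes=80,
                      seed=13)
    return generate_cell_line_panel(cfg)
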