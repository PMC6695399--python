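import numpy as np
import pandas as pd
import pytest

from crossmir.datamodel import GROUP_1, GROUP_2, ExpressionMatrix, SampleInfo
from crossmir.synthetic import SyntheticConfig, generate_study


def make_matrix(values, feature_ids=None, *, is_log2=False, assay="miRNA", compartment="cell"):
    """Small paired two-group matrix: first half of columns substate1, rest substate2."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    assert n_samp % 2 == 0
    n_rep = n_samp // 2
    samples = []
    for group in (GROUP_1, GROUP_2):
        for r in range(n_rep):
            samples.append(
                SampleInfo(
                    name=f"{group}_r{r + 1}",
                    group=group,
                    replicate_index=r + 1,
                    compartment=compartment,
                    assay=assay,
                )
            )
    if feature_ids is None:
        feature_ids = [f"F{i + 1}" for i in range(n_feat)]
    signals = pd.DataFrame(values, index=feature_ids, columns=[s.name for s in samples])
    return ExpressionMatrix(signals=signals, samples=samples, is_log2=is_log2)


@pytest.fixture(scope="session")
def default_config():
    return SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def default_study(default_config):
    return generate_study(default_config)


@pytest.fixture(scope="session")
def small_config():
    """A fast study for end-to-end structural tests."""
    return SyntheticConfig(
        n_genes=200,
        n_mirnas=60,
        n_de_genes_up=20,
        n_de_genes_down=20,
        n_de_mirnas_up=10,
        n_de_mirnas_down=10,
        n_biomarkers_up=5,
        n_biomarkers_down=2,
        targets_per_mirna=10,
        seed=11,
    )
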