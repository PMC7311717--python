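import numpy as np
import pandas as pd
import pytest

from neurochemnet import (
    ConcentrationTable,
    build_default_config,
    generate_dataset,
    impute_lloq,
    to_feature_matrix,
)


def make_table(spec: dict, panel: tuple[str, ...]) -> ConcentrationTable:
    """Build a toy table from {mouse_id: (state, {analyte: [v1, v2, ...]})}.

    NaN values are marked below_lloq (censored, not yet imputed).
    """
    rows = []
    for mouse, (state, analytes) in spec.items():
        for analyte, values in analytes.items():
            for i, v in enumerate(values, start=1):
                rows.append(
                    {
                        "mouse_id": mouse,
                        "state": state,
                        "sample_index": i,
                        "analyte": analyte,
                        "concentration_nM": v,
                        "below_lloq": bool(pd.isna(v)),
                        "imputed": False,
                    }
                )
    return ConcentrationTable(pd.DataFrame(rows), panel)


@pytest.fixture(scope="session")
def default_config():
    return build_default_config()

@pytest.fixture(scope="session")
def study_table(default_config):
    """One paper-scale synthetic dataset (fixed seed)."""
    return generate_dataset(default_config, seed=11)


@pytest.fixture(scope="session")
def imputed_table(default_config, study_table):
    table, _ = impute_lloq(study_table, default_config.lloq_nM)
    return table


@pytest.fixture(scope="session")
def features(imputed_table):
    return to_feature_matrix(imputed_table)


@pytest.fixture(scope="session")
def z_features(imputed_table):
    return to_feature_matrix(imputed_table, scaling="zscore")


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
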