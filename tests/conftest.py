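import numpy as np
import pandas as pd
import pytest

from cycifspatial import (
    assign_phenotypes,
    qc_filter,
    subtract_autofluorescence,
    zscore_normalize,
)
from cycifspatial import panels
from cycifspatial.simulate import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """10-core synthetic cohort with ground truth (the criterion-3 conditions)."""
    config = SyntheticConfig(seed=42, n_cores=10)
    cells, truth = generate_cohort(config)
    return config, cells, truth


@pytest.fixture(scope="session")
def gated_cohort(default_cohort):
    """The default cohort run through QC, normalization, and gating."""
    config, cells, truth = default_cohort
    out = qc_filter(cells)
    out = subtract_autofluorescence(out, panels.default_channel_map())
    out = zscore_normalize(out, grouping="per_core")
    out = assign_phenotypes(out, panels.default_gating_config())
    return config, out, truth


def make_cells(
    xy: np.ndarray,
    phenotypes,
    core_id: str = "C000",
    patient_id: str = "P000",
    **extra_columns,
) -> pd.DataFrame:
    """Hand-build a minimal cell table for targeted unit tests."""
    n = len(xy)
    df = pd.DataFrame(
        {
            "cell_id": [f"{core_id}_c{i:04d}" for i in range(n)],
            "core_id": core_id,
            "patient_id": patient_id,
            "x_um": np.asarray(xy, float)[:, 0],
            "y_um": np.asarray(xy, float)[:, 1],
            "phenotype": list(phenotypes),
        }
    )
    for col, vals in extra_columns.items():
        df[col] = vals
    return df
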