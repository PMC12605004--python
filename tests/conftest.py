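import numpy as np
import pandas as pd
import pytest

from omicnet.io import OmicsMatrix, SampleMetadata
from omicnet.simulate import SyntheticConfig, evenly_planted, generate_cohort


def make_matrix(values, kind="protein", sample_ids=None, feature_ids=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    sample_ids = sample_ids or [f"S{i}" for i in range(n)]
    feature_ids = feature_ids or [f"F{j}" for j in range(p)]
    frame = pd.DataFrame(values, index=sample_ids, columns=feature_ids)
    info = pd.DataFrame(
        {"kind": kind, "display_name": feature_ids, "platform_barcode": ""},
        index=pd.Index(feature_ids, name="feature_id"),
    )
    return OmicsMatrix(frame, info)


def make_metadata(groups, seed=0, **overrides):
    """Minimal valid metadata for a list of group labels."""
    rng = np.random.default_rng(seed)
    n = len(groups)
    frame = pd.DataFrame(
        {
            "group": groups,
            "sex": rng.choice(["F", "M"], n, p=[0.7, 0.3]),
            "age": rng.normal(58, 10, n),
            "bmi": rng.normal(29, 6, n),
            "smoking": rng.choice(
                ["NEVER_FORMER", "CURRENT", "UNKNOWN"], n, p=[0.9, 0.07, 0.03]
            ),
            "med_prednisone": False,
            "med_bdmard": False,
            "med_csdmard": False,
            "med_mtx": False,
            "esr": rng.gamma(2, 8, n),
            "crp": rng.gamma(2, 5, n),
            "das28crp": rng.normal(3.5, 1.2, n),
        },
        index=[f"S{i}" for i in range(n)],
    )
    for col, vals in overrides.items():
        frame[col] = vals
    return SampleMetadata(frame)


@pytest.fixture(scope="session")
def small_cohort():
    """40/group cohort with planted subgroup effects, modest dimensionality."""
    cfg = SyntheticConfig(
        n_per_group=40,
        n_proteins=60,
        n_metabolites=20,
        planted=evenly_planted(10, 1.2, 60, 20),
        seed=11,
    )
    return generate_cohort(cfg), cfg
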