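import numpy as np
import pandas as pd
import pytest

from sputumpanel.containers import MediatorMatrix
from sputumpanel.synthetic import GroupSpec, SimConfig, default_config, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One draw of the default two-cohort roster (censored matrix + metadata)."""
    return generate_cohort(default_config(seed=42))


@pytest.fixture(scope="session")
def small_cohort():
    """Compact three-group cohort, fully observed, for fast tests."""
    cfg = SimConfig(
        group_specs=[
            GroupSpec("A", 20),
            GroupSpec("B", 20, {"IL-8": 1.0}),
            GroupSpec("C", 20, {"IL-8": 2.0, "MMP-9": 1.5}),
        ],
        mediator_names=("IL-8", "MMP-9", "MPO", "CRP", "NE"),
        lod_quantile=0.0,
        seed=7,
    )
    return generate_cohort(cfg)


def make_matrix(values: np.ndarray, lod=None, mediators=None, scale="raw") -> MediatorMatrix:
    """Wrap a plain array into a MediatorMatrix with generated labels."""
    n, p = values.shape
    mediators = mediators or [f"M{j}" for j in range(p)]
    df = pd.DataFrame(values, index=[f"P{i:03d}" for i in range(n)], columns=mediators)
    lod_series = None
    if lod is not None:
        lod_series = pd.Series(np.asarray(lod, dtype=float), index=mediators)
    return MediatorMatrix(df, lod_series, scale)


def make_participants(groups: dict[str, int], seed=0, batch=None) -> pd.DataFrame:
    """Participant table with iid covariates for the given group sizes."""
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for g, n in groups.items():
        for _ in range(n):
            rows.append(
                {
                    "participant_id": f"P{i:03d}",
                    "group": g,
                    "batch": (batch or {}).get(g, "b1"),
                    "age": rng.normal(50, 10),
                    "sex": rng.choice(["female", "male"]),
                    "race": rng.choice(["white", "black", "other"]),
                    "bmi": rng.normal(27, 4),
                    "smoking_current": int(rng.random() < 0.4),
                    "cardiovascular": int(rng.random() < 0.3),
                    "pulmonary_vascular": int(rng.random() < 0.1),
                    "inhaled_steroid": int(rng.random() < 0.2),
                }
            )
            i += 1
    return pd.DataFrame(rows).set_index("participant_id")
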