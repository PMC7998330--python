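import numpy as np
import pandas as pd
import pytest

from twinherit import SimulationConfig, VarianceComponents, simulate_cohort
from twinherit.cohort_io import cohort_from_frame


@pytest.fixture
def small_cohort_frame():
    """Four complete pairs (2 MZ, 2 DZ), mixed sex, with one phenotype."""
    rows = []
    spec = [
        ("P1", "MZ", "F", 40.0, (1.01, 1.03)),
        ("P2", "MZ", "M", 55.0, (0.95, 0.93)),
        ("P3", "DZ", "F", 60.0, (1.10, 0.98)),
        ("P4", "DZ", "F", 47.0, (0.88, 0.91)),
    ]
    for pid, zyg, sex, age, (v1, v2) in spec:
        for idx, val in ((1, v1), (2, v2)):
            rows.append(
                {
                    "pair_id": pid,
                    "twin_index": idx,
                    "zygosity": zyg,
                    "sex": sex,
                    "age": age + idx * 0.0,
                    "bmi": 24.0 + idx,
                    "lumbar_bmd": val,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture
def small_cohort(small_cohort_frame):
    return cohort_from_frame(small_cohort_frame)


@pytest.fixture
def ae_cohort():
    """Simulated cohort with strong additive genetics and no shared environment."""
    cfg = SimulationConfig(
        n_mz_pairs=300,
        n_dz_pairs=300,
        components=VarianceComponents(a2=0.8, e2=0.2),
        seed=42,
    )
    return simulate_cohort(cfg)


def pair_arrays(cohort, values):
    """Per-zygosity (n, 2) arrays of a value series, ordered by twin index."""
    pairs = cohort.pairs(values)
    return {
        z: np.array([(p.value_1, p.value_2) for p in pairs[z]]).reshape(-1, 2)
        for z in ("MZ", "DZ")
    }
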