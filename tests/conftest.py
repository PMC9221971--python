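import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from succinylome.io import IntensityMatrix, SampleSheet

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture
def six_sample_sheet() -> SampleSheet:
    """Two groups (0h control, 8h treated) of three replicates."""
    return SampleSheet(
        {
            "0h_r1": ("0h", 1), "0h_r2": ("0h", 2), "0h_r3": ("0h", 3),
            "8h_r1": ("8h", 1), "8h_r2": ("8h", 2), "8h_r3": ("8h", 3),
        }
    )


def make_matrix(values: np.ndarray, samples: list[str]) -> IntensityMatrix:
    ids = [f"P{j + 1:03d}:K{10 * (j + 1)}" for j in range(values.shape[0])]
    return IntensityMatrix(
        values=pd.DataFrame(values, index=ids, columns=samples),
        features=pd.DataFrame(
            {"protein": [i.split(":")[0] for i in ids],
             "position": [int(i.split(":K")[1]) for i in ids]},
            index=ids,
        ),
    )


@pytest.fixture
def random_matrix_factory(six_sample_sheet):
    """Random positive 10x6 intensity matrices with optional missingness that
    always leaves >=2 observations per group per row."""

    def factory(seed: int, missing: bool = True) -> IntensityMatrix:
        rng = np.random.default_rng(seed)
        values = np.exp(rng.uniform(np.log(1e5), np.log(1e9), size=(10, 6)))
        if missing:
            for j in range(10):
                # knock out at most one sample per group
                for offset in (0, 3):
                    if rng.random() < 0.4:
                        values[j, offset + rng.integers(3)] = np.nan
        return make_matrix(values, six_sample_sheet.sample_ids)

    return factory
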