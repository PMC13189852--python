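import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from rarehap import AFSParams, HaplotypeMatrix, LegendTable, NvarParams, generate_haplotypes

settings.register_profile(
    "default",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def tiny_legend() -> LegendTable:
    return LegendTable(
        pd.DataFrame(
            {
                "id": ["v1", "v2", "v3"],
                "position": [10, 20, 30],
                "ref": ["A", "C", "G"],
                "alt": ["T", "G", "A"],
                "fun": ["functional", "functional", "synonymous"],
            }
        )
    )


@pytest.fixture
def tiny_matrix() -> HaplotypeMatrix:
    return HaplotypeMatrix(
        np.array(
            [
                [0, 1, 0, 0],
                [1, 0, 1, 0],
                [0, 0, 0, 1],
            ],
            dtype=np.uint8,
        )
    )


@pytest.fixture(scope="session")
def small_pool():
    """A seeded over-abundant pool: M=400 haplotypes over 2 kb."""
    matrix, legend = generate_haplotypes(
        M=400,
        region_kb=2.0,
        nvar=NvarParams(phi=1.0, omega=0.45),
        afs=AFSParams(alpha=1.0, beta=0.0, gamma=1.5),
        inflation=1.6,
        prop_fun=0.6,
        seed=99,
    )
    return matrix, legend
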