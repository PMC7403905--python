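import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from acunet.ingest import AliasTable, PrescriptionRecord

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def aliases() -> AliasTable:
    return AliasTable.default()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240612)


@pytest.fixture
def toy_records() -> list[PrescriptionRecord]:
    mk = PrescriptionRecord
    return [
        mk("D01", "case1", frozenset({"ST36", "LI4", "LR3"})),
        mk("D02", "case1", frozenset({"ST36", "LI4"})),
        mk("D03", "case1", frozenset({"LI4"})),
        mk("D01", "case2", frozenset({"ST36", "SP6", "PC6", "CV12"})),
        mk("D02", "case2", frozenset({"SP6", "PC6"})),
    ]


def random_records(rng: np.random.Generator, n_records: int = 50,
                   n_cases: int = 5, pool_size: int = 12,
                   max_size: int = 6) -> list[PrescriptionRecord]:
    """Random record collections for conservation/oracle checks."""
    pool = [f"ST{i + 1}" for i in range(pool_size)]
    records = []
    for i in range(n_records):
        case = f"case{rng.integers(1, n_cases + 1)}"
        size = int(rng.integers(1, max_size + 1))
        points = rng.choice(pool, size=size, replace=False)
        records.append(
            PrescriptionRecord(f"D{i:03d}", case, frozenset(points.tolist()))
        )
    return records


def random_count_matrix(rng: np.random.Generator, n_cases: int = 6,
                        n_acupoints: int = 15,
                        max_count: int = 40) -> pd.DataFrame:
    counts = rng.integers(0, max_count, size=(n_cases, n_acupoints))
    counts[:, 0] += 1  # keep every case's total positive
    return pd.DataFrame(
        counts,
        index=[f"case{i + 1}" for i in range(n_cases)],
        columns=[f"AP{i + 1:02d}" for i in range(n_acupoints)],
    )
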