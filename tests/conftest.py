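import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from osmodry.dataset import DesignTable, load_design_table, load_storage_series

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def table1() -> DesignTable:
    """The bundled 15-run reference experiment."""
    return load_design_table("table1")


@pytest.fixture(scope="session")
def storage_series():
    """The bundled storage-stability series (OD and ODC arms)."""
    return {s.arm: s for s in load_storage_series("table4")}


def make_table(columns: dict, factors: pd.DataFrame | None = None) -> DesignTable:
    """Assemble a small DesignTable from response columns (factors optional)."""
    n = len(next(iter(columns.values())))
    frame = pd.DataFrame({"run": np.arange(1, n + 1)})
    if factors is None:
        frame["T"] = np.linspace(20, 60, n)
        frame["Conc"] = np.linspace(60, 80, n)
        frame["t"] = np.linspace(1, 5, n)
    else:
        frame = pd.concat([frame, factors.reset_index(drop=True)], axis=1)
    for name, values in columns.items():
        frame[name] = np.asarray(values, dtype=float)
    return DesignTable(frame)


@pytest.fixture
def toy_table_factory():
    return make_table
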