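import numpy as np
import pytest

import catmetric as cm
from catmetric.naming import clean_records, table_from_records


@pytest.fixture(scope="session")
def model13():
    """The deterministic 13-name demo response model tiling the cube."""
    return cm.demo_model()


@pytest.fixture(scope="session")
def blurred13(model13):
    return cm.blur_field(model13.field(), delta=0.1)


@pytest.fixture(scope="session")
def grid13(blurred13):
    """Categorical tensor grid of the demo model (21^3 nodes, ~10 s)."""
    return cm.tensor_grid(blurred13, spacing=0.05, delta=0.1)


@pytest.fixture(scope="session")
def dataset13(model13):
    """Synthetic naming records drawn from the demo model (31/chip)."""
    return cm.synthetic_naming_dataset(model13, responses_per_chip=31, seed=11)


@pytest.fixture(scope="session")
def table13(dataset13):
    records, _ = clean_records(dataset13, {})
    return table_from_records(records)


@pytest.fixture(scope="session")
def handover_field():
    """Two-name complete handover along R, plateaus at both ends so the
    handover is strictly interior to the cube."""

    def rates(pts):
        s = np.clip((pts[:, 0] - 0.2) / 0.6, 0.0, 1.0)
        p1 = np.cos(np.pi * s / 2.0) ** 2
        return np.column_stack([p1, 1.0 - p1])

    return cm.CallableDistributionField(rates, ["a", "b"])
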