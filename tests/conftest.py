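import numpy as np
import pandas as pd
import pytest

from latewave.cohort import InviteeTable, VariableSchema


@pytest.fixture
def toy_table() -> InviteeTable:
    """Six invitees, three waves, one binary + one categorical variable."""
    df = pd.DataFrame(
        {
            "id": [1, 2, 3, 4, 5, 6],
            "wave": ["wave_0", "wave_0", "wave_1", "wave_2", "nonparticipant", "nonparticipant"],
            "smoker": [0.0, 1.0, 1.0, 0.0, 1.0, 0.0],
            "edu": ["A", "A", "B", "C", "C", None],
        }
    )
    schema = [
        VariableSchema("smoker", "binary"),
        VariableSchema("edu", "categorical", levels=("A", "B", "C"), missing_as_level=True),
    ]
    return InviteeTable(data=df, schema=schema, n_waves=3)


@pytest.fixture(scope="session")
def strokestop_cohort():
    """One medium synthetic cohort shaped like the AF-screening study."""
    from latewave.synthetic import generate_population, scenario_preset

    cfg = scenario_preset("strokestop_like", seed=7)
    table, truth = generate_population(cfg)
    return cfg, table, truth
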