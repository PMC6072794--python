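import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from conetstab import OtuTable

settings.register_profile("ci", deadline=None, max_examples=30, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def small_table():
    """3 taxa x 4 samples with distinct structure."""
    counts = pd.DataFrame(
        {
            "S1": [5, 3, 2],
            "S2": [1, 7, 2],
            "S3": [0, 4, 6],
            "S4": [2, 2, 6],
        },
        index=["tA", "tB", "tC"],
    )
    return OtuTable(counts)


@pytest.fixture
def meta_frame():
    rows = []
    for i, (tr, sa) in enumerate(
        [("control", "pre_drought"), ("control", "end_drought"),
         ("drought", "pre_drought"), ("drought", "end_drought")]
    ):
        rows.append(
            {"sample_id": f"S{i+1}", "treatment": tr, "sampling": sa,
             "block": i % 2 + 1, "plant_treatment": "P1"}
        )
    meta = pd.DataFrame(rows)
    from conetstab import validate_metadata

    return validate_metadata(meta)


def random_table(rng: np.random.Generator, n_taxa=12, n_samples=8, depth=200) -> OtuTable:
    p = rng.dirichlet(np.ones(n_taxa))
    counts = np.column_stack([rng.multinomial(depth, p) for _ in range(n_samples)])
    return OtuTable(
        pd.DataFrame(counts, index=[f"t{i}" for i in range(n_taxa)],
                     columns=[f"S{j}" for j in range(n_samples)])
    )
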