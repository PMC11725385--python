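import numpy as np
import pandas as pd
import pytest

from symdiv.div_overlay import VariantCountTable, build_registry

C15_PROFILE_NAMES = [
    "C15",
    "C15-C15dq",
    "C15-C15dq-C15dr",
    "C15-C15dq-C15dr-C_1365",
]


@pytest.fixture
def c15_registry():
    """The four nested, overlapping Cladocopium C15 DIV profiles."""
    return build_registry(C15_PROFILE_NAMES)


def make_table(rows: dict, variants: list[str]) -> VariantCountTable:
    """Build a VariantCountTable from {sample_id: [counts]}."""
    return VariantCountTable(
        data=pd.DataFrame.from_dict(
            rows, orient="index", columns=variants, dtype=np.int64
        ).rename_axis("sample_id")
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
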