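import pandas as pd
import pytest
from importlib.resources import files


@pytest.fixture(scope="session")
def cross_counts_table() -> pd.DataFrame:
    """Published cross counts with the printed TR / p columns retained."""
    path = files("drivekit.data").joinpath("f1_cross_transmission_counts.tsv")
    with path.open("rb") as fh:
        return pd.read_csv(fh, sep="\t", comment="#")
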