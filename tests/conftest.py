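import numpy as np
import pandas as pd
import pytest

from magflux.iodata import ProfileMatrix, SampleKey, reference_plant


@pytest.fixture
def plant():
    """The full-scale AGS plant configuration used in worked examples."""
    return reference_plant()


@pytest.fixture
def make_profiles():
    """Factory: build a ProfileMatrix from {column-key-string: values}."""

    def build(columns: dict, kind: str = "metagenomics", mag_ids=None) -> ProfileMatrix:
        n = len(next(iter(columns.values())))
        if mag_ids is None:
            mag_ids = [f"MAG_{i:03d}" for i in range(1, n + 1)]
        data = pd.DataFrame(
            {SampleKey.parse(k): np.asarray(v, dtype=float) for k, v in columns.items()},
            index=pd.Index(mag_ids, name="mag_id"),
        )
        return ProfileMatrix(data, kind)

    return build


@pytest.fixture
def balanced_profiles(make_profiles):
    """A 3-MAG, 1-replicate table covering every compartment."""
    return make_profiles(
        {
            "influent.rep1": [0.10, 0.00, 0.02],
            "AGS.mixed.rep1": [0.05, 0.03, 0.00],
            "excess_sludge.rep1": [0.04, 0.02, 0.00],
            "effluent.rep1": [0.01, 0.01, 0.00],
        }
    )
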