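import numpy as np
import pandas as pd
import pytest

from recoverkit import ReferenceAmplicon


def make_plate_table(readouts, controls, replicate=1, plate_id="P01", condition="treated"):
    """One plate: sample wells (gene GENE001..) plus negative-control wells."""
    rows = []
    for i, x in enumerate(controls):
        rows.append(
            dict(plate_id=plate_id, well_id=f"C{i:02d}", gene="LUC", sirna_id="pool",
                 condition=condition, replicate=replicate, readout=x,
                 is_control="negative_control")
        )
    for i, x in enumerate(readouts):
        rows.append(
            dict(plate_id=plate_id, well_id=f"W{i:02d}", gene=f"GENE{i + 1:03d}",
                 sirna_id="pool", condition=condition, replicate=replicate, readout=x,
                 is_control="none")
        )
    return pd.DataFrame(rows)


@pytest.fixture
def five_well_plate():
    """Five sample wells at 0.1..0.5 and one control; m=0.3, s=0.1581."""
    return make_plate_table([0.1, 0.2, 0.3, 0.4, 0.5], controls=[0.3])


@pytest.fixture
def toy_reference():
    return ReferenceAmplicon(sequence="AAAACCGGTTTT", cut_position=6, name="toy")


@pytest.fixture
def rng():
    return np.random.default_rng(42)
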