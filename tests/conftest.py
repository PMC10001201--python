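import sys
from pathlib import Path

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def simple_plate() -> pd.DataFrame:
    """One model: vehicle wells at 9000/11000, one drugged condition at 4000/6000."""
    return pd.DataFrame(
        {
            "model_id": "M1",
            "compound": ["vehicle", "vehicle", "drugA", "drugA"],
            "dose_uM": [0.0, 0.0, 1.0, 1.0],
            "replicate": [1, 2, 1, 2],
            "signal": [9000.0, 11000.0, 4000.0, 6000.0],
            "role": ["vehicle", "vehicle", "sample", "sample"],
        }
    )
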