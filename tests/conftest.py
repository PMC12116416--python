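import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def meas_table(tmp_path):
    """Small two-animal long-format measurement table on disk."""
    p = tmp_path / "meas.tsv"
    p.write_text(
        "model_id\tanimal_id\tarm\tstudy_day\tvolume_mm3\n"
        "M1\ta1\tvehicle\t0\t250\n"
        "M1\ta2\ttreated\t0\t240\n"
        "M1\ta1\tvehicle\t2\t380\n"
        "M1\ta2\ttreated\t2\t200\n"
        "M1\ta1\tvehicle\t4\t560\n"
        "M1\ta2\ttreated\t4\t180\n"
    )
    return p
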