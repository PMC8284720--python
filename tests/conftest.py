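import numpy as np
import pytest

from metabnet import Region, RegionAtlas, UptakeTable


@pytest.fixture(scope="session")
def atlas96():
    return RegionAtlas.default()


@pytest.fixture
def tiny_atlas():
    return RegionAtlas(
        [
            Region(1, "region a", "A", "L"),
            Region(2, "region b", "B", "R"),
            Region(3, "region c", "C", "L"),
            Region(4, "region d", "D", "R"),
        ]
    )


@pytest.fixture
def make_table():
    """Factory for uptake tables with auto-generated subject ids."""

    def _make(values, atlas, condition="pre"):
        values = np.asarray(values, dtype=float)
        subjects = tuple(f"s{i:02d}" for i in range(values.shape[0]))
        return UptakeTable(condition, subjects, values, atlas)

    return _make


try:
    from hypothesis import HealthCheck, settings

    settings.register_profile(
        "metabnet",
        deadline=None,
        derandomize=True,
        suppress_health_check=[HealthCheck.too_slow],
    )
    settings.load_profile("metabnet")
except ImportError:  # pragma: no cover
    pass
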