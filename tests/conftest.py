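import numpy as np
import pytest

from rescuemap.io import PlateSeries
from rescuemap.trajectory import AnalysisConfig, AncestralReference


@pytest.fixture
def cfg():
    return AnalysisConfig()


@pytest.fixture
def ref():
    return AncestralReference(mean_norm_yfp=100.0, mean_norm_cfp=100.0, n_wells=95)


@pytest.fixture
def make_series():
    """Factory for a PlateSeries from per-day (od, yfp, cfp) triples."""

    def _make(readings, plate_id="p1", well="A01"):
        od, yfp, cfp = (np.array(col, dtype=float) for col in zip(*readings))
        return PlateSeries(
            plate_id=plate_id,
            well=well,
            days=np.arange(1, len(od) + 1),
            od600=od,
            yfp=yfp,
            cfp=cfp,
        )

    return _make
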