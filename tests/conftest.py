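import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from nucmir.containers import ExpressionMatrix
from nucmir.simulate import triplicate_meta

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def meta6():
    """Triplicate nuclear + cytoplasmic sample sheet (N1-3, C1-3)."""
    return triplicate_meta(3)


@pytest.fixture
def make_matrix(meta6):
    """Build an ExpressionMatrix from a probe x 6-sample array."""

    def _make(values, probe_ids=None, meta=None):
        values = np.atleast_2d(np.asarray(values, dtype=float))
        meta = meta or meta6
        probe_ids = probe_ids or [f"p{i}" for i in range(values.shape[0])]
        df = pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"),
                          columns=[m.sample_id for m in meta])
        return ExpressionMatrix(df, meta)

    return _make
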