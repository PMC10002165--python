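import numpy as np
import pytest

from iegnet import ExpressionTable, default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def small_registry(registry):
    """Five-ROI registry for fast structural tests."""
    return registry.subset(["LSV", "Tu", "MS", "IG", "CPDM"])


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def table_factory():
    """Build an ExpressionTable from a values matrix."""

    def make(values, group="G", rois=None):
        values = np.asarray(values, dtype=float)
        n, m = values.shape
        rois = rois if rois is not None else [f"R{j}" for j in range(m)]
        animals = [f"{group}_a{i}" for i in range(n)]
        return ExpressionTable(group=group, animals=animals, rois=list(rois), values=values)

    return make
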