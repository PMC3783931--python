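"""Shared fixtures: synthetic phantom cases and their pipeline results.

The default phantom (20 mL core nested in 100 mL hypoperfusion, 6 s delay,
right side) is expensive enough to share at session scope; tests that need
different lesion geometry build their own config.
"""

import numpy as np
import pytest

from strokemismatch.phantom import PhantomConfig, generate_stroke_phantom
from strokemismatch.pipeline import assess_case


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(bool)
    b = b.astype(bool)
    denom = a.sum() + b.sum()
    return 2.0 * np.sum(a & b) / denom if denom else float("nan")


@pytest.fixture(scope="session")
def default_phantom():
    return generate_stroke_phantom(PhantomConfig(seed=7))


@pytest.fixture(scope="session")
def default_assessment(default_phantom):
    ph = default_phantom
    return assess_case(ph.b0, ph.b1000, ph.dsc, record=ph.record)


@pytest.fixture(scope="session")
def symmetric_phantom():
    return generate_stroke_phantom(PhantomConfig(seed=11, side="none"))
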