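import numpy as np
import pytest

import polytail as pt


@pytest.fixture(scope="session")
def panel160():
    """The bundled 160-SNP synthetic effect panel (var(WAS) = 0.10)."""
    return pt.bundled_panel()


@pytest.fixture
def small_panel():
    """A 10-SNP panel with mixed signs for hand-checkable score math."""
    rng = np.random.default_rng(42)
    freqs = rng.uniform(0.1, 0.9, 10)
    betas = rng.normal(0, 0.05, 10)
    return pt.SnpPanel(
        pt.SnpEffect(f"rs{i}", "A", "G", float(betas[i]), 0.005, float(freqs[i]))
        for i in range(10)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
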