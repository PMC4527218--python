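import numpy as np
import pandas as pd
import pytest

from scwga import (
    GenomeLayout,
    MethodProfile,
    simulate_golden_control,
)


@pytest.fixture(scope="session")
def layout():
    return GenomeLayout.example()


@pytest.fixture(scope="session")
def small_control(layout):
    return simulate_golden_control(
        5_000, (0.72, 0.12, 0.16), layout, seed=11
    )


@pytest.fixture()
def quiet_profile():
    """No-noise method profile: every site covered, no ADO/FP events."""
    return MethodProfile(
        name="quiet", ado_rate=0.0, fp_rate=0.0, site_coverage=1.0,
        bin_dispersion=0.0, chimera_rate=0.0,
    )


@pytest.fixture()
def flat_track():
    n = 50
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n) * 100_000,
            "end": (np.arange(n) + 1) * 100_000,
            "depth": 10.0,
            "gc": np.linspace(0.25, 0.60, n),
        }
    )
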