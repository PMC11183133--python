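import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from chestgait import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_bundle():
    """Six-subject study with shortened sessions, shared across tests."""
    cfg = SimulationConfig(
        n_subjects=6,
        walk_task_duration_s=25.0,
        inlab_activity_duration_s=100.0,
        outside_activity_duration_s=160.0,
        seed=42,
    )
    return simulate_study(cfg)
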