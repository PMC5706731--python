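"""Shared fixtures: seed-batched network runs reused across test modules.

Network conditions are simulated once per test session at the scaled-down
profile (1.5 s odor, dt = 20 us, 5 seeds) and cached, since several
criteria are read off the same runs.
"""

from __future__ import annotations

import numpy as np
import pytest

from obnet import scenarios
from obnet.engine import SimulationConfig

QUICK_SEEDS = (1, 2, 3, 4, 5)


def quick_base() -> SimulationConfig:
    return scenarios.quick_profile()


@pytest.fixture(scope="session")
def network_runs():
    """Factory returning cached ScenarioResults at the quick profile."""
    cache: dict[str, scenarios.ScenarioResult] = {}

    def get(name: str, keep_recordings: bool = False) -> scenarios.ScenarioResult:
        key = f"{name}|rec" if keep_recordings else name
        if key not in cache:
            cache[key] = scenarios.run_scenario(
                name,
                seeds=QUICK_SEEDS,
                base=quick_base(),
                keep_recordings=keep_recordings,
            )
        return cache[key]

    return get
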