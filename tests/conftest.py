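import numpy as np
import pytest
from hypothesis import settings

from sheltersim.scenario import KennelTier, Scenario, TrackProfile, example_scenario

settings.register_profile("suite", deadline=None, max_examples=60, derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def shelter():
    """The bundled two-track, four-tier example shelter (S priority)."""
    return example_scenario()


def random_scenario(rng: np.random.Generator, force_unbounded: bool | None = None) -> Scenario:
    """Draw a random valid scenario for property tests.

    2-4 tiers (optionally ending in an unbounded overflow tier), 1-3
    tracks with baseline LOS in [2, 40] and intake rates in [0, 3].
    """
    n_tiers = int(rng.integers(2, 5))
    unbounded = bool(rng.random() < 0.7) if force_unbounded is None else force_unbounded
    tiers = []
    for i in range(n_tiers):
        last = i == n_tiers - 1
        tiers.append(
            KennelTier(
                name=f"tier{i}",
                capacity=None if (last and unbounded) else int(rng.integers(1, 30)),
                multiplier=float(rng.uniform(0.3, 4.0)),
                rank=i + 1,
            )
        )
    n_tracks = int(rng.integers(1, 4))
    tracks = [
        TrackProfile(
            name=f"track{j}",
            baseline_los=float(rng.uniform(2.0, 40.0)),
            intake_rate=float(rng.uniform(0.0, 3.0)),
        )
        for j in range(n_tracks)
    ]
    priority = "S" if rng.random() < 0.5 else "F"
    return Scenario(tiers=tuple(tiers), tracks=tuple(tracks), priority=priority)
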