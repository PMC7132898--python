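import numpy as np
import pytest

from nphtest.core import SurvivalDataset


@pytest.fixture
def small_mixed_dataset():
    """Ten subjects, both arms, ties and censoring."""
    return SurvivalDataset(
        time=np.array([1.0, 2.0, 2.0, 3.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]),
        event=np.array([1, 1, 0, 1, 1, 0, 1, 0, 1, 0]),
        arm=np.array([0, 1, 0, 1, 0, 1, 1, 0, 0, 1]),
    )


@pytest.fixture
def make_random_dataset():
    """Factory for random small two-arm datasets with events in both arms."""

    def _make(seed, n_max=30):
        rng = np.random.default_rng(seed)
        while True:
            n = int(rng.integers(8, n_max + 1)) & ~1
            time = rng.exponential(1.0, n)
            if rng.random() < 0.5:  # induce ties on a coarse grid
                time = np.ceil(time * 4) / 4
            event = (rng.random(n) < 0.75).astype(int)
            arm = np.repeat([0, 1], n // 2)
            d = SurvivalDataset(time, event, arm)
            ev = d.event == 1
            if ev.any() and len(set(d.arm[ev])) == 2 and d.n_events >= 3:
                return d

    return _make
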