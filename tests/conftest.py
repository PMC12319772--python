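import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_predicate():
    """A small dropout-free grounded predicate for exact-gradient work."""
    from nesyqsar.nn import MLP, NetworkSpec
    from nesyqsar.real_logic import GroundedPredicate

    net = MLP(NetworkSpec((4, 6, 2), "relu", 0.0), seed=3)
    return GroundedPredicate(net)


@pytest.fixture
def blob_data():
    """Well-separated two-class Gaussian fixture, scaled, split 70/10/20."""
    from nesyqsar.curation import standard_scale
    from nesyqsar.synthetic import simulate_separable_features

    x, y, _ = simulate_separable_features(n=400, dim=8, separation=6.0, seed=99)
    split = np.array(["train"] * 280 + ["val"] * 40 + ["test"] * 80)
    xs, _ = standard_scale(x, split)
    return {
        "train": (xs[:280], y[:280]),
        "val": (xs[280:320], y[280:320]),
        "test": (xs[320:], y[320:]),
    }
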