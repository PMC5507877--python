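import os
import sys

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, os.path.dirname(__file__))  # make tests/oracle.py importable

from concatseq.archmodel import ArchitectureSpec, default_adapter
from concatseq.deconcat import ScanParams
from concatseq.simulate import NmerDistribution, SimConfig, random_panel

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def adapter():
    return default_adapter()


@pytest.fixture(scope="session")
def arch():
    return ArchitectureSpec()


@pytest.fixture(scope="session")
def scan_params(adapter):
    return ScanParams(adapter=adapter)


@pytest.fixture(scope="session")
def panel4():
    return random_panel(4, target_len=120, seed=42)


def _make_config(panel, **overrides):
    """A clean (error-free, artifact-free) config unless overridden."""
    kwargs = dict(
        architecture=ArchitectureSpec(),
        panel=panel,
        n_reads=100,
        nmer=NmerDistribution("geometric", 5, 50),
        sub_rate=0.0,
        ins_rate=0.0,
        del_rate=0.0,
        hairpin_remnant_prob=0.0,
        end_truncation_prob=0.0,
        hybrid_prob=0.0,
        seed=1,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def make_config(panel4):
    def factory(**overrides):
        panel = overrides.pop("panel", panel4)
        return _make_config(panel, **overrides)

    return factory


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20170712)
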