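"""Shared fixtures: one desk-scale synthetic study reused across tests."""

from __future__ import annotations

import pytest

from stressmir.config import SyntheticConfig
from stressmir.pipeline import run_pipeline
from stressmir import synthetic


def small_config(seed: int = 1, **overrides) -> SyntheticConfig:
    base = dict(
        seed=seed,
        library_sizes={"control": 20_000, "drought": 20_000, "salt": 20_000},
        n_known_mirnas=12,
        n_novel_mirnas=4,
        n_contigs=10,
        n_background=150,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def config():
    return small_config()


@pytest.fixture(scope="session")
def reference(config):
    return synthetic.generate_reference(config)


@pytest.fixture(scope="session")
def libraries(config, reference):
    return synthetic.simulate_libraries(config, reference)


@pytest.fixture(scope="session")
def pipeline(config):
    """Full pipeline run on a fresh copy of the study (own truth ledger)."""
    return run_pipeline(small_config())
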