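"""Shared fixtures: tetrad builders, small maps, and heavy simulations.

The 50k-tetrad simulations are session-scoped so that the mapping,
interference, assurance and acceptance tests all reuse the same draws.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tetracross as tc

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

N_BIG = 50_000


def make_tetrad(tid: str, spore_codes, viable=(True, True, True, True)) -> tc.Tetrad:
    """Build a tetrad from per-spore call strings, e.g. ['PPP','PPM',...]."""
    return tc.Tetrad(
        tid,
        tuple(
            tc.SporeGenotype.from_codes(sid, v, codes)
            for sid, v, codes in zip("abcd", viable, spore_codes)
        ),
    )


@pytest.fixture(scope="session")
def map3() -> tc.MarkerMap:
    """Three evenly spaced markers, centromere at the left marker."""
    return tc.MarkerMap.from_markers("T", [("X", 0.0), ("Y", 10.0), ("Z", 20.0)], 0)


@pytest.fixture(scope="session")
def map4() -> tc.MarkerMap:
    return tc.MarkerMap.from_markers(
        "T", [("X", 0.0), ("Y", 10.0), ("Z", 20.0), ("W", 30.0)], 0
    )


@pytest.fixture(scope="session")
def chr3() -> tc.MarkerMap:
    return tc.chr3_map()


def clean_config(**kwargs) -> tc.SimConfig:
    """A simulation with no conversion, death or nondisjunction noise."""
    base = dict(
        n_tetrads=N_BIG,
        co_model="poisson",
        interference_m=0,
        obligate_CO=False,
        assurance_fail_q=0.0,
        conversion_prob=0.0,
        backup_efficiency=1.0,
        spore_death_rate=0.0,
        seed=1,
    )
    base.update(kwargs)
    return tc.SimConfig(**base)


@pytest.fixture(scope="session")
def sim_nointf():
    """50k tetrads, Poisson crossovers, no interference, no noise."""
    return tc.simulate_tetrads(clean_config())


@pytest.fixture(scope="session")
def sim_counting():
    """50k tetrads under strong counting-model interference (m=4)."""
    return tc.simulate_tetrads(clean_config(co_model="counting", interference_m=4, seed=2))


@pytest.fixture(scope="session")
def sim_mixture():
    """Interference-positive cells plus a forced-achiasmate fraction q=0.15."""
    return tc.simulate_tetrads(
        clean_config(
            co_model="counting",
            interference_m=4,
            obligate_CO=True,
            assurance_fail_q=0.15,
            seed=3,
        )
    )


@pytest.fixture(scope="session")
def tallies_nointf(sim_nointf, chr3):
    return tc.tally_intervals(sim_nointf.tetrads, chr3)


@pytest.fixture(scope="session")
def tallies_counting(sim_counting, chr3):
    return tc.tally_intervals(sim_counting.tetrads, chr3)
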