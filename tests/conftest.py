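from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from exomesv.model import GeneModel, Group, InheritanceMode
from exomesv.prioritize import run_prioritization
from exomesv.simulate import SimConfig, simulate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_bundle():
    """The synthetic cohort under its default study conditions."""
    return simulate_cohort(SimConfig())


@pytest.fixture(scope="session")
def default_result(default_bundle):
    """Full cascade output on the default bundle."""
    return run_prioritization(default_bundle.callsets,
                              default_bundle.samples,
                              default_bundle.genes,
                              short_variants=default_bundle.short_variants)


@pytest.fixture(scope="session")
def small_bundle():
    """A quick 30-family bundle for unit-level checks."""
    return simulate_cohort(SimConfig(n_families=30, seed=11))


@pytest.fixture
def toy_gene():
    """One gene with three exons on chromosome 1."""
    return GeneModel("TOY1", "1", "+",
                     exons=[(1000, 1199), (5000, 5299), (9000, 9399)],
                     panels={Group.NMD},
                     inheritance_modes={InheritanceMode.AD})
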