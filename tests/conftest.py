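"""Shared fixtures: small phantoms for unit tests, one cached study context.

The evaluation-grade pipeline runs (full mesh densities) are expensive, so
they are computed once per session in a shared ``StudyContext`` and reused
by every test that scores the end-to-end study.
"""

import numpy as np
import pytest

from oeseit import (
    PhantomSpec,
    StudyConfig,
    adjacent_protocol,
    assign_conductivity,
    build_phantom,
    run_fig4,
    run_sweep,
    run_table1,
)
from oeseit.pipeline import StudyContext


@pytest.fixture(scope="session")
def protocol16():
    return adjacent_protocol(16)


@pytest.fixture(scope="session")
def small_external():
    """Coarse external phantom with the D=0.1 target at offset 0.5."""
    spec = PhantomSpec(arrangement="external", target_offset=0.5)
    mesh, electrodes = build_phantom(spec, 2500, seed=7)
    return spec, mesh, electrodes


@pytest.fixture(scope="session")
def small_internal():
    spec = PhantomSpec(arrangement="internal", target_offset=0.5)
    mesh, electrodes = build_phantom(spec, 2500, seed=7)
    return spec, mesh, electrodes


@pytest.fixture(scope="session")
def small_homogeneous():
    """Coarse external phantom without lungs or target (homogeneous tank)."""
    spec = PhantomSpec(
        arrangement="external", target_diameter=0.0, include_lungs=False
    )
    mesh, electrodes = build_phantom(spec, 2500, seed=7)
    sigma = assign_conductivity(mesh, spec)
    return spec, mesh, electrodes, sigma


@pytest.fixture(scope="session")
def study_ctx():
    return StudyContext()


@pytest.fixture(scope="session")
def table1_result(study_ctx):
    """The arrangement comparison at offset 0.5 under the default seed."""
    return run_table1(StudyConfig(seed=0), study_ctx)


@pytest.fixture(scope="session")
def sweep_result(study_ctx):
    """The full 2 x 7 position sweep under the default seed."""
    return run_sweep(StudyConfig(seed=0), study_ctx)


@pytest.fixture(scope="session")
def fig4_result(study_ctx):
    """The deep-target (D=0.2) image pair and intensity ratio."""
    return run_fig4(StudyConfig(seed=0), study_ctx)
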