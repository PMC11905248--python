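"""Shared fixtures: phantoms at three desk scales.

All fixtures are generated programmatically (no stored data).  The
expensive registration-recovery experiment is computed once per session and
shared between the module-level and acceptance-level checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from doseaccum.phantom import (
    DeformationSpec,
    PhantomSpec,
    generate_daily_case,
    generate_planning_case,
)
from doseaccum.registration import (
    make_focus_box,
    register_hybrid_deformable,
    register_rigid,
)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Coarse 48^3 phantom (4 mm) for fast structural checks."""
    return PhantomSpec(seed=1).scaled((48, 48, 48))


@pytest.fixture(scope="session")
def small_case(small_spec):
    return generate_planning_case(small_spec)


@pytest.fixture(scope="session")
def med_spec() -> PhantomSpec:
    """64^3 phantom (3 mm) used for the registration experiments."""
    return PhantomSpec(seed=1).scaled((64, 64, 64))


@pytest.fixture(scope="session")
def med_case(med_spec):
    return generate_planning_case(med_spec)


@pytest.fixture(scope="session")
def default_case_128():
    """The full default-resolution planning phantom (128^3, 1.5 mm)."""
    return generate_planning_case(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def deformed_daily(med_case):
    """Daily case with a 5 mm smooth truth field on the 64^3 phantom."""
    deform = DeformationSpec(seed=7, random_field_amp_mm=5.0)
    return generate_daily_case(med_case, deform, fraction_index=1)


@pytest.fixture(scope="session")
def recovery(med_case, deformed_daily):
    """Rigid + hybrid deformable registration of the deformed daily case.

    Shared session-wide: the ground-truth-field recovery experiment backs
    several independent assertions.
    """
    box = make_focus_box(med_case.structures["PTV_eval"], med_case.grid)
    rigid = register_rigid(med_case.image, deformed_daily.image, box)
    result = register_hybrid_deformable(
        med_case.image,
        deformed_daily.image,
        med_case.structures,
        deformed_daily.structures,
        init=rigid,
        box=box,
    )
    return {"box": box, "rigid": rigid, "result": result}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
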