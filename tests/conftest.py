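import pytest

import irepulse as ip
from irepulse.verification import (  # noqa: F401  (re-exported for tests)
    coax_exact,
    make_annulus_domain,
    make_slab_domain,
)


@pytest.fixture(scope="session")
def study_domain_coarse():
    """Default study geometry at a 1 mm grid (fast shared fixture)."""
    return ip.build_domain(ip.CylinderSpec(), ip.ElectrodePairSpec(), 1.0)


@pytest.fixture(scope="session")
def study_field_coarse(study_domain_coarse):
    return ip.solve_potential(study_domain_coarse)
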