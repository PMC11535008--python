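import math

import numpy as np
import pytest

from singtrap import (Compartment, CompartmentConfiguration, DomainSpec,
                      make_greens_provider)


@pytest.fixture(scope="session")
def disk_domain():
    return DomainSpec("disk2d", (1.0,), D=1.0, gamma0=1.0)


@pytest.fixture(scope="session")
def disk_provider(disk_domain):
    return make_greens_provider(disk_domain)


@pytest.fixture(scope="session")
def disk0_domain():
    return DomainSpec("disk2d", (1.0,), D=1.0, gamma0=0.0)


@pytest.fixture(scope="session")
def disk0_provider(disk0_domain):
    return make_greens_provider(disk0_domain)


@pytest.fixture(scope="session")
def sphere_domain():
    return DomainSpec("sphere3d", (1.0,), D=1.0, gamma0=1.0)


@pytest.fixture(scope="session")
def sphere_provider(sphere_domain):
    return make_greens_provider(sphere_domain)


@pytest.fixture(scope="session")
def rect_domain():
    return DomainSpec("rect2d", (1.3, 1.0), D=1.0, gamma0=2.0)


@pytest.fixture(scope="session")
def rect_provider(rect_domain):
    return make_greens_provider(rect_domain)


@pytest.fixture(scope="session")
def box_domain():
    return DomainSpec("box3d", (1.0, 1.2, 1.1), D=1.0, gamma0=1.5)


@pytest.fixture(scope="session")
def box_provider(box_domain):
    return make_greens_provider(box_domain)


def concentric_config(eps=0.02, kappa=math.inf, c0=1.0, gamma0=1.0,
                      kind="disk2d"):
    dom = DomainSpec(kind, (1.0,), D=1.0, gamma0=gamma0)
    dim = dom.dim
    return CompartmentConfiguration(
        dom, eps, [Compartment(np.zeros(dim), 1.0, kappa, "I", c0=c0)])
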