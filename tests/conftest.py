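import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gatekit.toysim import (
    ToyChannelSpec,
    default_landscape,
    make_toy_channel,
    synthetic_kcsa,
    toy_selection_spec,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_system():
    """(spec, closed, open, energy) for the default toy channel."""
    spec = ToyChannelSpec()
    closed, open_, energy = make_toy_channel(spec)
    return spec, closed, open_, energy


@pytest.fixture(scope="session")
def toy_selection():
    return toy_selection_spec()


@pytest.fixture(scope="session")
def landscape():
    return default_landscape()


@pytest.fixture(scope="session")
def kcsa_standins():
    """Synthetic closed/intermediate/open stand-in tetramers."""
    return {
        state: synthetic_kcsa(state)
        for state in ("closed", "intermediate", "open")
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)


def cylinder_model(R=0.8, nz=9, nring=8, twist=0.3):
    """Bead rings of radius R stacked along z: the analytic pore fixture."""
    from gatekit.structio import StructureModel

    coords = []
    for iz, z in enumerate(np.linspace(-1.0, 1.0, nz)):
        for a in np.linspace(0, 2 * np.pi, nring, endpoint=False):
            coords.append(
                [R * np.cos(a + twist * iz), R * np.sin(a + twist * iz), z]
            )
    n = len(coords)
    return StructureModel(
        serial=np.arange(1, n + 1),
        atom_name=np.array(["CA"] * n),
        residue_name=np.array(["ALA"] * n),
        residue_seq=np.arange(1, n + 1),
        chain_id=np.array(["A"] * n),
        element=np.array(["C"] * n),
        coords=np.array(coords),
    )


@pytest.fixture()
def cylinder():
    return cylinder_model()
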