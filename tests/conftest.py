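import numpy as np
import pytest

from ligandprobe import (
    MapSynthesisSpec,
    StructureModel,
    build_femo_fixture,
    synthesize_map,
)
from ligandprobe.model_map_io import AtomRecord


@pytest.fixture(scope="session")
def femo():
    """Idealized chain-A FeMo cluster fixture."""
    return build_femo_fixture("A")


@pytest.fixture(scope="session")
def femo_boxed():
    """FeMo cluster centred in a small P1 box, for structure factors."""
    return build_femo_fixture("A", cell=(14, 14, 14, 90, 90, 90), center=(7, 7, 7))


def single_atom_model(element="S", n_electrons=None, b_iso=15.0):
    return StructureModel(
        [AtomRecord(1, element.upper(), element, "A", "LIG", 1,
                    np.zeros(3), b_iso=b_iso, n_electrons=n_electrons)],
        (20, 20, 20, 90, 90, 90),
    )


@pytest.fixture(scope="session")
def single_s_map():
    """Noiseless map of one neutral S atom (16 e, B = 15), 0.25 A spacing."""
    spec = MapSynthesisSpec(model=single_atom_model(), grid_spacing=0.25, padding=4.0)
    return synthesize_map(spec)
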