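import numpy as np
import pytest

from dendrospike.biophysics import (
    CellBiophysics,
    DensityRule,
    PassiveProperties,
    SpineCorrectionRule,
    _build_channel,
    ca1_biophysics,
    ca2_biophysics,
    load_kinetics,
)
from dendrospike.morphology import (
    Morphology,
    MorphogenParams,
    Point3D,
    Section,
    generate_morphology,
)
from dendrospike.simulator import SimulationConfig, discretize, initialize


def make_passive_biophysics(spine_factor: float = 1.0) -> CellBiophysics:
    """All active densities zero; optional uniform spine factor."""
    kin = load_kinetics()
    zero = DensityRule(kind="uniform", base=0.0)
    channels = tuple(_build_channel(n, kin[n], zero) for n in ("Na", "Kdr", "KA", "H"))
    rule = SpineCorrectionRule(150.0, max(spine_factor, 1.0), max(spine_factor, 1.0))
    return CellBiophysics("ca2", PassiveProperties(), rule, channels)


def make_stick(length: float = 400.0, diameter: float = 2.0,
               soma_diameter: float = 15.0) -> Morphology:
    """Soma plus one straight apical cable."""
    r = soma_diameter / 2
    secs = {
        "soma": Section("soma", "soma",
                        [Point3D(0, -r, 0, soma_diameter), Point3D(0, r, 0, soma_diameter)]),
        "apical_trunk": Section(
            "apical_trunk", "apical_trunk",
            [Point3D(0, r, 0, diameter), Point3D(0, r + length, 0, diameter)],
            parent=("soma", 1.0)),
    }
    return Morphology(secs, "soma")


def make_soma_only(diameter: float = 15.0) -> Morphology:
    r = diameter / 2
    return Morphology(
        {"soma": Section("soma", "soma",
                         [Point3D(0, -r, 0, diameter), Point3D(0, r, 0, diameter)])},
        "soma",
    )


@pytest.fixture(scope="session")
def ca2_morph():
    return generate_morphology(MorphogenParams(cell_class="ca2", seed=1))


@pytest.fixture(scope="session")
def ca1_morph():
    return generate_morphology(MorphogenParams(cell_class="ca1", seed=1))


@pytest.fixture(scope="session")
def ca2_model(ca2_morph):
    model = discretize(ca2_morph, ca2_biophysics(), 10.0)
    return initialize(model, SimulationConfig(settle=50.0))


@pytest.fixture(scope="session")
def ca1_model(ca1_morph):
    model = discretize(ca1_morph, ca1_biophysics(), 10.0)
    return initialize(model, SimulationConfig(settle=50.0))
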