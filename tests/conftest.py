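import pytest

from ghkfit import (
    ActivityModel,
    ChannelModel,
    KineticsSpec,
    NoiseSpec,
    PhysicalContext,
    VoltageProtocol,
    build_solution,
    registry,
    salt,
)


@pytest.fixture(scope="session")
def ctx():
    return PhysicalContext()  # 22 °C


@pytest.fixture(scope="session")
def unity():
    return ActivityModel(mode="unity")


@pytest.fixture(scope="session")
def davies():
    return ActivityModel(mode="davies")


@pytest.fixture(scope="session")
def solutions():
    return registry()


@pytest.fixture(scope="session")
def dilution_externals(solutions):
    return [
        (1.0, solutions["1NaCl"]),
        (0.5, solutions["0.5NaCl"]),
        (0.25, solutions["0.25NaCl"]),
    ]


@pytest.fixture
def anion_channel():
    return ChannelModel({"Na": 1.0, "Cl": 18.8}, conductance_scale=0.1)


@pytest.fixture
def cation_channel():
    """Cation-converted channel: Na+ and K+ alike, residual Cl-, no Ca2+."""
    return ChannelModel({"Na": 1.0, "K": 1.0, "Cl": 0.19, "Ca": 0.0},
                        conductance_scale=0.1)


@pytest.fixture
def protocol():
    return VoltageProtocol()


@pytest.fixture
def kinetics():
    return KineticsSpec(tau_d_ms=100.0, plateau_fraction=0.3)


@pytest.fixture
def quiet_noise():
    return NoiseSpec(trace_noise_sd=0.0, replicate_amplitude_cv=0.0, seed=0)


def make_monovalent_solution(name, side, na_mM, cl_mM):
    """Bath/pipette with arbitrary independent Na+ and Cl- totals.

    The shared part comes from NaCl; excess Na+ is added as Na-gluconate and
    excess Cl- as NMDG-Cl, keeping every salt electroneutral.
    """
    shared = min(na_mM, cl_mM)
    comps = [salt("NaCl", shared)]
    if na_mM > shared:
        comps.append(salt("Na-gluconate", na_mM - shared))
    if cl_mM > shared:
        comps.append(salt("NMDG-Cl", cl_mM - shared))
    return build_solution(name, side, comps)
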