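import pytest

from skinpain.transduction import simulate_membrane

# On-axis transduction stresses for the reference geometry (a = 10 mm):
# q = 25 kPa at depth 1.6 mm and q = 35 kPa at depth 1.6 mm, and a
# sub-threshold case.  Shared session-wide because each simulation costs
# about a second.
SIGMA_Q25 = 24.957840
SIGMA_Q35 = 34.940975
SIGMA_SUBTHRESHOLD = 15.0


@pytest.fixture(scope="session")
def spiking_trace():
    """Membrane trace for the q = 25 kPa reference scenario (supra-threshold)."""
    return simulate_membrane(SIGMA_Q25)


@pytest.fixture(scope="session")
def spiking_trace_strong():
    """Membrane trace for the q = 35 kPa reference scenario."""
    return simulate_membrane(SIGMA_Q35)


@pytest.fixture(scope="session")
def silent_trace():
    """Membrane trace below the mechanical threshold (no stimulus current)."""
    return simulate_membrane(SIGMA_SUBTHRESHOLD)
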