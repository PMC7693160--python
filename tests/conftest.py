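import pytest

from flupbpk.drug import flurbiprofen
from flupbpk.media import (AqueousSolubilityModel, MEDIA_REGISTRY,
                           SolubilityMeasurement)

# Table of equilibrium solubilities (medium, final pH, ug/mL) used across
# the solubility-fitting tests: aqueous buffers and fasted biorelevant media.
AQUEOUS_ROWS = [("FaSSGF_I", 1.6, 18.1), ("acetate_4.5", 4.7, 101.1),
                ("FeSSIF_V1_I", 5.1, 225.4), ("phosphate_6.5", 6.1, 2024.4),
                ("phosphate_6.8", 6.3, 3127.1)]
BIORELEVANT_ROWS = [("FaSSGF_III", 1.6, 18.5), ("FaSSIF_V1_II", 6.0, 1954.9),
                    ("FaSSIF_V3_II", 5.9, 1585.4)]


@pytest.fixture(scope="session")
def drug():
    return flurbiprofen()


@pytest.fixture(scope="session")
def aq_model():
    return AqueousSolubilityModel(S0=18.1, pKa=4.05)


@pytest.fixture(scope="session")
def aqueous_measurements():
    return [SolubilityMeasurement(m, p, s) for m, p, s in AQUEOUS_ROWS]


@pytest.fixture(scope="session")
def biorelevant_measurements():
    return [SolubilityMeasurement(m, p, s) for m, p, s in BIORELEVANT_ROWS]


@pytest.fixture(scope="session")
def biorelevant_media():
    return [MEDIA_REGISTRY[m] for m, _, _ in BIORELEVANT_ROWS]


@pytest.fixture(scope="session")
def reference_oral(drug):
    """One reference-subject 100 mg IR-tablet simulation, reused widely."""
    from flupbpk.pbpk import simulate_pk
    return simulate_pk(drug, dose=100.0, t_end=30.0)
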