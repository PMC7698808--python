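import pytest

from specprofiler import (
    ExperimentDesign,
    parse_peptide,
    simulate_lcms,
)
from specprofiler import datasets


@pytest.fixture(scope="session")
def hek_design():
    return ExperimentDesign.hek_screen()


@pytest.fixture(scope="session")
def tryptic_design():
    return ExperimentDesign.tryptic_screen()


@pytest.fixture(scope="session")
def hek_substrates():
    return datasets.load_hek_substrates()


@pytest.fixture(scope="session")
def hek_products():
    return datasets.load_hek_products()


@pytest.fixture(scope="session")
def tryptic_table():
    return datasets.load_tryptic_table()


#: 20-peptide library for end-to-end recovery: C-termini span strong (Arg),
#: partial (Lys) and null cleavage, with favorable and unfavorable P1
#: contexts and one precursor/product pair present together.
END_TO_END_LIBRARY = [
    "GQEFTITGQKR",
    "AVKQFEESQGR",
    "AELEQLKGQGKSR",
    "Ac-ADEIAKAQVAR",
    "YGGFMKR",
    "KVPQVSTPTLVEVSR",
    "IIEPSLR",
    "ALEQATR",
    "NMDVPNIKR",
    "HHQKLVFFAR",
    "HHQKLVFFAK",
    "ALEQATRK",
    "TLNFDGGK",
    "SDGRGGSK",
    "ARLSQKFPKAE",
    "VFDVELL",
    "EKTPKTPKGPSSV",
    "TTTTTFKGVDPNSD",
    "AVGSGSKGKGGEIQPVSV",
    "GQEFTITGQK",
]


@pytest.fixture(scope="session")
def e2e_library():
    return [parse_peptide(s) for s in END_TO_END_LIBRARY]


@pytest.fixture(scope="session")
def e2e_experiment(e2e_library):
    return simulate_lcms(e2e_library, noise_cv=0.05, seed=20)
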