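import warnings

import pytest

from gcannotate.chem_core import parse_formula
from gcannotate.evidence import MatchWeighting
from gcannotate.scoring_engine import annotate_run
from gcannotate.spectra_io import AlkaneCalibration, Spectrum
from gcannotate.synthetic_data import SimConfig, generate_library, generate_run


@pytest.fixture
def water():
    return parse_formula("H2O")


@pytest.fixture
def benzene():
    return parse_formula("C6H6")


@pytest.fixture
def calibration():
    """Alkanes C8..C14 at 1 min per carbon."""
    return AlkaneCalibration(tuple((c, float(c)) for c in range(8, 15)))


@pytest.fixture
def simple_spectrum():
    return Spectrum.from_pairs([(50.015, 100.0), (77.039, 40.0), (105.07, 10.0)])


@pytest.fixture(scope="session")
def small_sim():
    """A small, fully-controlled spike-recovery study shared across tests."""
    config = SimConfig(
        seed=7,
        n_compounds=40,
        n_true_spikes=12,
        n_decoys=8,
        n_contaminants=4,
        n_samples=4,
        n_blanks=4,
    )
    library = generate_library(config)
    run = generate_run(library, config)
    return config, run


@pytest.fixture(scope="session")
def small_annotations(small_sim):
    _, run = small_sim
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return annotate_run(
            run.features,
            run.library,
            run.calibration,
            weighting=MatchWeighting.accurate(10.0),
        )
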