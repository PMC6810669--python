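import numpy as np
import pandas as pd
import pytest

import myoaging as ma


@pytest.fixture(scope="session")
def cohort12():
    """Study-layout cohort: 60 donors, 12 TMT batches."""
    return ma.simulate_cohort(12, seed=7)


@pytest.fixture(scope="session")
def cohort4():
    """Small cohort for fast pipeline tests: 20 donors, 4 batches."""
    return ma.simulate_cohort(4, seed=11)


@pytest.fixture(scope="session")
def toy_annotation(tmp_path_factory):
    """Planted 14-gene annotation written to disk, with its ground truth."""
    text, events = ma.make_toy_annotation()
    path = tmp_path_factory.mktemp("ann") / "toy.gtf"
    path.write_text(text)
    return path, events


@pytest.fixture(scope="session")
def clean_spectra(cohort4):
    """Noisy but complete (no missing, no flagged) spectra for 80 proteins."""
    truth = ma.simulate_protein_truth(80, seed=3)
    spectra = ma.simulate_tmt_spectra(
        cohort4, truth, missing_rate=0.0, seed=4,
        decoy_frac=0.0, contaminant_frac=0.0, shared_frac=0.0,
    )
    return spectra, truth
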