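import numpy as np
import pandas as pd
import pytest

from hypercyte import cytogate, synthdata

MIXED_FRACTIONS = {"G1": 0.50, "S": 0.15, "G2": 0.20, "HYPER": 0.15}


@pytest.fixture(scope="session")
def mixed_population():
    """5000-cell population with a substantial hyperploid class."""
    spec = synthdata.PopulationSpec(
        n_cells=5000, class_fractions=dict(MIXED_FRACTIONS), dna_cv=0.06, seed=11
    )
    truth, records = synthdata.generate_population(spec)
    return spec, truth, records


@pytest.fixture(scope="session")
def fitted_gates(mixed_population):
    _, _, records = mixed_population
    return cytogate.fit_gateset(records)


@pytest.fixture(scope="session")
def mixed_labels(mixed_population, fitted_gates):
    _, _, records = mixed_population
    return cytogate.apply_gateset(records, fitted_gates)


@pytest.fixture(scope="session")
def rendered_field():
    """One rendered 512x512 field of 50 nuclei with default noise."""
    spec = synthdata.PopulationSpec(n_cells=50, seed=5)
    truth, records = synthdata.generate_population(spec)
    cells = truth.merge(records.drop(columns=["area"]), on="cell_id")
    imaging = synthdata.ImagingSpec(field_size=(512, 512))
    images, labels, placed = synthdata.render_field(cells, imaging, seed=5)
    return images, labels, placed
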