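import numpy as np
import pytest

from rdcsas.rdc_model import RDCDataset, RDCRecord, precompute_matrix
from rdcsas.structures import HelixSpec, build_aform_helix
from rdcsas.synthetic_data import (JunctionModel, SimulatedTruth,
                                   generate_library, random_tensor,
                                   simulate_rdc_dataset)


@pytest.fixture(scope="session")
def helix_spec():
    return HelixSpec("GCAG", "CUGC", (18, 19, 20, 21), (41, 42, 43, 44))


@pytest.fixture(scope="session")
def helix(helix_spec):
    return build_aform_helix(helix_spec)


@pytest.fixture(scope="session")
def junction_model():
    return JunctionModel(seed=11)


@pytest.fixture(scope="session")
def small_problem(junction_model):
    """60-conformer library with a planted 3-member ensemble and a
    noise-free 3-construct dataset plus its prediction matrix."""
    library = generate_library(junction_model, 60)
    rng = np.random.default_rng(7)
    true_members = sorted(rng.choice(60, size=3, replace=False).tolist())
    cids = ["cA", "cB", "cC"]
    truth = SimulatedTruth(
        true_member_indices=true_members,
        true_tensors={c: random_tensor(rng) for c in cids},
        true_scales={c: float(rng.uniform(0.7, 1.3)) for c in cids},
        noise_sd=0.0)
    dataset = simulate_rdc_dataset(library, truth, cids, 30,
                                   model=junction_model, seed=3)
    matrix = precompute_matrix(library, dataset, mode="fixed-tensor",
                               tensors=truth.true_tensors)
    return {"library": library, "dataset": dataset, "matrix": matrix,
            "truth": truth}
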