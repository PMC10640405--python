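import warnings

import numpy as np
import pytest

from microbiont.simulate import StudyDesign, simulate_study
from microbiont.trees import parse_newick


@pytest.fixture(scope="session")
def three_tip_tree():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def four_tip_tree():
    return parse_newick("((A:1,B:1):1.2,(C:1.5,D:1.5):0.7);")


@pytest.fixture(scope="session")
def asv_distances_3():
    """Contrasting patristic distances for 3 ASVs (two close, one far)."""
    return np.array([[0.0, 0.3, 1.8], [0.3, 0.0, 1.7], [1.8, 1.7, 0.0]])


@pytest.fixture(scope="session")
def synthetic_study():
    """One seeded synthetic preset study shared across tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table, history, truth, manifest = simulate_study(seed=42)
    return {"table": table, "history": history, "truth": truth,
            "manifest": manifest}
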