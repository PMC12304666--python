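import numpy as np
import pytest

from funcresp import ExperimentDesign, PredationTrial


@pytest.fixture
def toy_trials():
    """A fixed 12-trial dataset (densities 2,4,8,16 x 3 replicates).

    Counts drawn once from the second-instar design and frozen, so the NLS
    grid-search oracle has a stable target.
    """
    n0s = [2, 2, 2, 4, 4, 4, 8, 8, 8, 16, 16, 16]
    nas = [2, 1, 2, 3, 2, 3, 4, 5, 3, 6, 4, 5]
    return [
        PredationTrial(predator_instar=2, treatment="control", n0=n0, na=na, replicate_id=i + 1)
        for i, (n0, na) in enumerate(zip(n0s, nas))
    ]


@pytest.fixture
def ladder2():
    return ExperimentDesign(densities=(2, 4, 8, 16))
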