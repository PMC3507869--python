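import numpy as np
import pandas as pd
import pytest

from epimsap.msap_core import MSAPMatrix
from epimsap.synthetic_data import simulate_msap_population, study_cohort_spec


def make_matrix(values, enzyme="HpaII", line_ids=None, generations=None):
    """Small MSAPMatrix builder for hand-written fixtures."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    samples = [f"s{i + 1}" for i in range(n)]
    loci = [f"L{j + 1}" for j in range(p)]
    frame = pd.DataFrame(values, index=samples, columns=loci)
    lines = line_ids if line_ids is not None else ["line1"] * n
    gens = generations if generations is not None else ["E2"] * n
    return MSAPMatrix(
        values=frame,
        line_ids=pd.Series(lines, index=samples),
        generations=pd.Series(gens, index=samples),
        enzyme=enzyme,
    )


@pytest.fixture(scope="session")
def study_cohort():
    """One realisation of the 14-line MSAP sampling design (seeded)."""
    return simulate_msap_population(study_cohort_spec(rng_seed=11))
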