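import warnings

import numpy as np
import pytest

from multibdwi import BValueScheme, BiexpParams, StretchedParams
from multibdwi.pipeline import run_study

# Table-style group means used repeatedly as ground truths (mm^2/s).
PROG_BIEXP = BiexpParams(d=1.084e-3, d_star=53.841e-3, f=0.333)
PSEUDO_BIEXP = BiexpParams(d=1.741e-3, d_star=25.613e-3, f=0.239)
PROG_STRETCHED = StretchedParams(ddc=1.177e-3, alpha=0.673)
PSEUDO_STRETCHED = StretchedParams(ddc=1.692e-3, alpha=0.879)


@pytest.fixture(scope="session")
def scheme() -> BValueScheme:
    return BValueScheme()


@pytest.fixture(scope="session")
def study():
    """One full synthetic study run (simulate -> fit -> measure -> report).

    Session-scoped because the whole-cohort fit dominates suite runtime;
    several tests inspect different layers of the same run.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_study(seed=1)
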