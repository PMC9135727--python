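import numpy as np
import pandas as pd
import pytest

from immlnc import synthdata


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort shared by tests that only need realistic structure."""
    return synthdata.simulate(
        n_samples=120, n_mrna=800, n_lnc=150, n_pathways=6, seed=11
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the generator's default study conditions."""
    return synthdata.simulate(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def toy_bundle():
    """Tiny hand-built bundle: 2 mRNAs, 1 lncRNA, 4 samples."""
    from immlnc.iodata import ExpressionBundle

    samples = ["s1", "s2", "s3", "s4"]
    return ExpressionBundle(
        lnc_expr=pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["lncA"], columns=samples),
        mrna_expr=pd.DataFrame(
            [[4.0, 3.0, 2.0, 1.0], [1.0, 3.0, 2.0, 5.0]],
            index=["geneA", "geneB"],
            columns=samples,
        ),
        purity=pd.Series([0.5, 0.6, 0.7, 0.8], index=samples, name="purity"),
    )
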