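import numpy as np
import pytest

import irscreen as ir


@pytest.fixture
def tiny_dataset():
    """2 samples x 3 replicates on a 5-point grid, labelled."""
    wn = np.array([1000.0, 1100.0, 1200.0, 1300.0, 1400.0])
    rng = np.random.default_rng(42)
    rows = rng.normal(1.0, 0.1, size=(6, 5))
    return ir.SpectralDataset(
        wavenumbers=wn,
        absorbance=rows,
        sample_ids=np.array(["A", "A", "A", "B", "B", "B"], dtype=object),
        replicate_ids=np.array([1, 2, 3, 1, 2, 3]),
        labels=np.array([1, 1, 1, 0, 0, 0]),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Small synthetic cohort shared by slower tests (fingerprint grid only)."""
    cfg = ir.GeneratorConfig(n_samples=60, seed=7, grid_lo=900, grid_hi=1800)
    return ir.generate(cfg)


@pytest.fixture(scope="session")
def preprocessed_cohort(small_cohort):
    ds, truth = small_cohort
    dsp, _ = ir.preprocess(ir.average_replicates(ds))
    return dsp, truth
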