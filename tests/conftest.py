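import numpy as np
import pytest

from tatashift import datasets, pipeline
from tatashift.affinity import AffinityModelParams, DINUCLEOTIDES


@pytest.fixture(scope="session")
def default_params():
    return datasets.default_params()


@pytest.fixture(scope="session")
def calibrated_params():
    """Coefficients fitted once against the packaged tables' WT K_D column."""
    return pipeline.run_calibrate()


@pytest.fixture(scope="session")
def marker_records():
    return datasets.load_marker_records()


@pytest.fixture(scope="session")
def gene_rules():
    return datasets.load_gene_rules()


@pytest.fixture()
def toy_params():
    """Small transparent model: W=3, hand-readable tables."""
    rng = np.random.default_rng(7)
    slide = {d: float(v) for d, v in zip(DINUCLEOTIDES, rng.normal(size=16))}
    bend = {d: float(v) for d, v in zip(DINUCLEOTIDES, rng.normal(size=16))}
    pwm = rng.normal(size=(3, 4))
    return AffinityModelParams(
        slide_table=slide,
        pwm=pwm,
        bend_table=bend,
        coeffs=(1.0, 0.5, -1.0, 0.25),
        residual_se=0.3,
        window_len=3,
    )
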