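import numpy as np
import pytest

from yieldsurf import SurfaceTruth, fit_quadratic, load_fixture


@pytest.fixture(scope="session")
def bbd17():
    return load_fixture("bbd17")


@pytest.fixture(scope="session")
def fitted(bbd17):
    return fit_quadratic(bbd17.dataset)


@pytest.fixture(scope="session")
def surface_truth(bbd17, fitted):
    """The fitted reference surface as a synthetic ground truth, with the
    replicate-derived noise level (sqrt of the pure-error mean square)."""
    return SurfaceTruth(
        coefficients=tuple(fitted.coef),
        noise_sd=float(np.sqrt(9.52)),
        factors=bbd17.dataset.factors,
    )
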