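import numpy as np
import pytest

from gweistat import BINOMIAL, GAUSSIAN, DesignBundle, fit_null


@pytest.fixture(scope="session")
def gaussian_fixture():
    """n=200 gaussian bundle: intercept + covariate + environment null."""
    rng = np.random.default_rng(42)
    n = 200
    z = rng.standard_normal(n)
    e = rng.standard_normal(n)
    y = rng.standard_normal(n)
    Z = np.column_stack([np.ones(n), z, e])
    X = np.column_stack([np.ones(n), e])
    bundle = DesignBundle(y=y, Z=Z, X=X, family=GAUSSIAN)
    return bundle, fit_null(bundle)


@pytest.fixture(scope="session")
def binomial_fixture():
    rng = np.random.default_rng(43)
    n = 200
    z = rng.standard_normal(n)
    e = rng.standard_normal(n)
    y = rng.binomial(1, 0.5, n).astype(float)
    Z = np.column_stack([np.ones(n), z, e])
    X = np.column_stack([np.ones(n), e])
    bundle = DesignBundle(y=y, Z=Z, X=X, family=BINOMIAL)
    return bundle, fit_null(bundle)


@pytest.fixture(scope="session")
def large_gaussian_fixture():
    """n=1000 gaussian bundle used by calibration/oracle checks."""
    rng = np.random.default_rng(7)
    n = 1000
    z = rng.standard_normal(n)
    e = rng.standard_normal(n)
    y = rng.standard_normal(n)
    Z = np.column_stack([np.ones(n), z, e])
    X = np.column_stack([np.ones(n), e])
    bundle = DesignBundle(y=y, Z=Z, X=X, family=GAUSSIAN)
    return bundle, fit_null(bundle)


@pytest.fixture(scope="session")
def large_binomial_fixture():
    rng = np.random.default_rng(8)
    n = 1000
    z = rng.standard_normal(n)
    e = rng.standard_normal(n)
    y = rng.binomial(1, 0.5, n).astype(float)
    Z = np.column_stack([np.ones(n), z, e])
    X = np.column_stack([np.ones(n), e])
    bundle = DesignBundle(y=y, Z=Z, X=X, family=BINOMIAL)
    return bundle, fit_null(bundle)
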