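import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from stiidil.core import (
    FeatureKind,
    FeatureMeta,
    FeatureSpace,
    PatientState,
    Regimen,
    ValueFunction,
)


def make_lab_patient(
    d: int,
    seed: int = 0,
    values=None,
    baseline=None,
    missing=None,
) -> PatientState:
    """Generic patient over d anonymous lab features, for estimator tests."""
    rng = np.random.default_rng(seed)
    feats = [FeatureMeta(i, f"f{i}", FeatureKind.LAB) for i in range(d)]
    if values is None:
        values = rng.normal(size=d)
    if baseline is None:
        baseline = rng.normal(size=d)
    if missing is None:
        missing = np.zeros(d, dtype=bool)
    return PatientState(
        space=FeatureSpace(feats),
        values=np.asarray(values, dtype=float),
        missing_mask=np.asarray(missing, dtype=bool),
        baseline=np.asarray(baseline, dtype=float),
        regimen=Regimen.PRELUNCH_SHORT,
    )


def linear_vf(weights) -> ValueFunction:
    w = np.asarray(weights, dtype=float)
    return ValueFunction(
        predict=lambda z: float(w @ z), gradient=lambda z: w.copy(), name="linear"
    )


def product_vf() -> ValueFunction:
    return ValueFunction(
        predict=lambda z: float(z[0] * z[1]),
        gradient=lambda z: np.array([z[1], z[0]] + [0.0] * (len(z) - 2)),
        name="product",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
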