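import numpy as np
import pytest

from oligoring import sec

# The five-protein calibration set of a 24 ml analytical gel-filtration
# column (void 8.4 ml): (name, mass kDa, elution volume ml).
CALIBRATION_STANDARDS = [
    ("beta-amylase", 200.0, 12.3),
    ("alcohol dehydrogenase", 150.0, 13.3),
    ("bovine serum albumin", 66.0, 14.3),
    ("ovalbumin", 43.0, 15.7),
    ("carbonic anhydrase", 29.0, 16.8),
]


@pytest.fixture(scope="session")
def column():
    return sec.ColumnConstants(vo=8.4, vt=24.0)


@pytest.fixture(scope="session")
def standards():
    return [sec.CalibrationStandard(n, m, v) for n, m, v in CALIBRATION_STANDARDS]


@pytest.fixture(scope="session")
def calibration(standards, column):
    return sec.fit_calibration(standards, column)


def ols_oracle(x, y):
    """Normal-equations least squares, independent of the fitting code."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    a = np.column_stack([x, np.ones_like(x)])
    slope, intercept = np.linalg.solve(a.T @ a, a.T @ y)
    return float(slope), float(intercept)
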