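import numpy as np
import pytest

from nirspt.design import build_timeline, generate_trial_set
from nirspt.glm import canonical_hrf
from nirspt.montage import build_montage, default_roi_map


@pytest.fixture(scope="session")
def montage():
    return build_montage()


@pytest.fixture(scope="session")
def roi_map():
    return default_roi_map()


@pytest.fixture(scope="session")
def trials():
    return generate_trial_set(1)


@pytest.fixture(scope="session")
def timeline(trials):
    return build_timeline(trials, [2500.0] * 24, seed=2)


@pytest.fixture(scope="session")
def hrf():
    return canonical_hrf()


def type3_anova_oracle(y, p, c):
    """Independent Type III sums of squares via model comparison.

    Fits the full sum-to-zero-coded 2x2 OLS model and each reduced model
    dropping one effect; SS_effect is the residual-sum-of-squares increase.
    """
    y = np.asarray(y, dtype=float)
    pv = np.where(np.asarray(p) == sorted(set(p))[0], 1.0, -1.0)
    cv = np.where(np.asarray(c) == sorted(set(c))[0], 1.0, -1.0)
    X = np.column_stack([np.ones_like(y), pv, cv, pv * cv])

    def rss(cols):
        b, *_ = np.linalg.lstsq(X[:, cols], y, rcond=None)
        r = y - X[:, cols] @ b
        return float(r @ r)

    full = rss([0, 1, 2, 3])
    df_err = len(y) - 4
    out = {}
    for name, cols in (
        ("perspective", [0, 2, 3]),
        ("consistency", [0, 1, 3]),
        ("interaction", [0, 1, 2]),
    ):
        ss = rss(cols) - full
        out[name] = {"ss": ss, "F": ss / (full / df_err)}
    out["error"] = {"ss": full, "df": df_err}
    return out
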