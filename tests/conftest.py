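import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from cueshift.synthetic_data import orientation_columns


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trials(
    ori: np.ndarray,
    cue="neutral",
    stim=None,
    block_type="pre",
    valid=None,
    subject=1,
) -> pd.DataFrame:
    """Assemble a trial table from an (n, n_frames) orientation array."""
    ori = np.atleast_2d(np.asarray(ori, dtype=float))
    n = len(ori)

    def _col(v, default):
        if v is None:
            v = default
        return list(v) if not np.isscalar(v) and not isinstance(v, str) else [v] * n

    cues = _col(cue, "neutral")
    if stim is None:
        stims = ["right" if ori[i].mean() > 0 else "left" for i in range(n)]
    else:
        stims = _col(stim, None)
    if valid is None:
        valids = [pd.NA if c == "neutral" else (c == s) for c, s in zip(cues, stims)]
    else:
        valids = _col(valid, None)
    df = pd.DataFrame(
        {
            "subject": subject,
            "trial": np.arange(n),
            "run": 1,
            "block": 1,
            "block_type": _col(block_type, "pre"),
            "cue": cues,
            "stim": stims,
            "valid": pd.array(valids, dtype="boolean"),
        }
    )
    df[orientation_columns(ori.shape[1])] = ori
    return df


def brute_force_logit_slope(x, y, grid_half_width=15.0, grid_points=61):
    """Independent maximizer of the Bernoulli log-likelihood of an
    intercept + slope logistic model: coarse grid search followed by
    Nelder-Mead refinement.  Shares no code with the package's fitter."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def nll(params):
        b0, b1 = params
        eta = b0 + b1 * x
        # log(1 + exp(eta)) computed stably
        return float(np.sum(np.logaddexp(0.0, eta) - y * eta))

    grid = np.linspace(-grid_half_width, grid_half_width, grid_points)
    best, best_val = (0.0, 0.0), np.inf
    for b0 in grid:
        for b1 in grid:
            v = nll((b0, b1))
            if v < best_val:
                best, best_val = (b0, b1), v
    res = minimize(nll, best, method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 5000})
    return float(res.x[1])
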