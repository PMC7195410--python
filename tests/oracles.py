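"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (explicit loops, no shared code with
the package) against which the optimised implementations are checked.
"""

import numpy as np


def brute_simplex(series, E, tau, tp):
    """Leave-one-out simplex forecast by exhaustive neighbour search.

    Returns (rho, rmse). Embedding row at time t = (x_t, x_{t-tau}, ...,
    x_{t-(E-1)tau}); target x_{t+tp}; E+1 nearest neighbours by Euclidean
    distance excluding the query itself; weights exp(-d/d_min) (uniform
    over exact matches when d_min == 0).
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    offset = (E - 1) * tau
    times = [t for t in range(offset, n) if 0 <= t + tp < n]
    points = {t: np.array([x[t - k * tau] for k in range(E)])
              for t in times}
    preds, obs = [], []
    for t in times:
        dists = sorted(
            (np.linalg.norm(points[t] - points[s]), s)
            for s in times if s != t
        )
        nbrs = dists[: E + 1]
        d_min = nbrs[0][0]
        if d_min == 0:
            w = np.array([1.0 if d == 0 else 0.0 for d, _ in nbrs])
        else:
            w = np.array([np.exp(-d / d_min) for d, _ in nbrs])
        w = w / w.sum()
        preds.append(sum(wi * x[s + tp] for wi, (_, s) in zip(w, nbrs)))
        obs.append(x[t + tp])
    preds, obs = np.array(preds), np.array(obs)
    rmse = float(np.sqrt(np.mean((preds - obs) ** 2)))
    if np.std(preds) == 0 or np.std(obs) == 0:
        return np.nan, rmse
    return float(np.corrcoef(preds, obs)[0, 1]), rmse
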