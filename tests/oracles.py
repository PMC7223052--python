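"""Independent reference implementations used only as test oracles.

The naive second-order CFA fit below shares no code with the package
engine: the implied matrix is built element by element from first
principles and the discrepancy is minimized by a generic quasi-Newton run
with numerically differenced gradients.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def naive_second_order_fit(R, indicator_map, indicators, factors):
    """Element-wise ML fit of the second-order model to a correlation matrix.

    Returns (lam, beta, theta, F_min) with signs aligned so loading sums
    and the beta sum are positive.
    """
    p, K = len(indicators), len(factors)
    kidx = [factors.index(indicator_map[j]) for j in indicators]
    _, ld_r = np.linalg.slogdet(R)

    def sigma_of(x):
        lam, beta, theta = x[:p], x[p:p + K], x[p + K:]
        S = np.empty((p, p))
        for a in range(p):
            for b in range(p):
                ka, kb = kidx[a], kidx[b]
                fcov = 1.0 if ka == kb else beta[ka] * beta[kb]
                S[a, b] = lam[a] * lam[b] * fcov + (theta[a] if a == b else 0.0)
        return S

    def objective(x):
        S = sigma_of(x)
        sign, ld = np.linalg.slogdet(S)
        if sign <= 0:
            return 1e6
        return ld + np.trace(np.linalg.solve(S, R)) - ld_r - p

    x0 = np.concatenate([np.full(p, 0.5), np.full(K, 0.5), np.full(p, 0.5)])
    bounds = [(-2, 2)] * p + [(-0.999, 0.999)] * K + [(1e-6, None)] * p
    res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 5000, "ftol": 1e-14})
    lam = res.x[:p].copy()
    beta = res.x[p:p + K].copy()
    theta = res.x[p + K:].copy()
    kidx_arr = np.array(kidx)
    for k in range(K):
        mask = kidx_arr == k
        if lam[mask].sum() < 0:
            lam[mask] *= -1
            beta[k] *= -1
    if beta.sum() < 0:
        beta *= -1
    return lam, beta, theta, float(res.fun)
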