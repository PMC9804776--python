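"""Independent brute-force maximiser of the restricted likelihood.

Used only as a test oracle: evaluates the restricted log-likelihood on a
coarse grid over the variance components (one or two of them) and refines
the best grid point with derivative-free Nelder-Mead.  Shares no code
path with the package's quasi-Newton fitter beyond the likelihood
definition itself, which is cross-checked separately against metafor.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import optimize

from phylometa.mlmeta import ModelSpec, reml_loglik


def brute_force_reml(spec: ModelSpec, upper: float = 1.0, grid_size: int = 40):
    """Grid search + Nelder-Mead refinement over <= 2 components."""
    k = len(spec.random_terms)
    if k > 2:
        raise ValueError("oracle supports at most two variance components")
    axis = np.concatenate([[0.0], np.geomspace(1e-6, upper, grid_size)])
    best_val, best_point = -np.inf, np.zeros(k)
    for point in itertools.product(axis, repeat=k):
        val = reml_loglik(point, spec)
        if val > best_val:
            best_val, best_point = val, np.array(point)

    def negll(raw):
        return -reml_loglik(np.maximum(raw, 0.0), spec)

    res = optimize.minimize(
        negll,
        best_point,
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
    )
    refined = np.maximum(res.x, 0.0)
    if -res.fun < best_val:
        refined = best_point
    return refined, reml_loglik(refined, spec)
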