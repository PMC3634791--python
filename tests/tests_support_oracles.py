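"""Independent numerical oracles shared by the test suite."""

import math

import numpy as np
from scipy.optimize import minimize


def numerical_z_oracle(left, right) -> float:
    """log10 likelihood ratio of the two-mean vs one-mean Gaussian model,
    obtained by direct numerical maximization of both likelihoods (no use
    of the closed form)."""
    left = np.asarray(left, float)
    right = np.asarray(right, float)
    y = np.concatenate([left, right])
    n = len(y)

    def negll_het(params):
        m1, m2, logs = params
        s2 = math.exp(2 * logs)
        ss = np.sum((left - m1) ** 2) + np.sum((right - m2) ** 2)
        return 0.5 * n * math.log(2 * math.pi * s2) + ss / (2 * s2)

    def negll_hom(params):
        m, logs = params
        s2 = math.exp(2 * logs)
        return 0.5 * n * math.log(2 * math.pi * s2) + np.sum((y - m) ** 2) / (2 * s2)

    opts = {"xtol": 1e-14, "ftol": 1e-15, "maxiter": 100000, "maxfev": 100000}
    r1 = minimize(
        negll_het,
        [left.mean() + 0.01, right.mean() - 0.01, math.log(y.std() + 0.05)],
        method="Powell",
        options=opts,
    )
    r0 = minimize(
        negll_hom, [y.mean() + 0.01, math.log(y.std() + 0.05)], method="Powell", options=opts
    )
    return (r0.fun - r1.fun) / math.log(10)


def brute_force_shared_interval(haps: np.ndarray, anchor: int) -> tuple[int, int]:
    """Widest marker interval containing the anchor over which every
    haplotype row is identical (missing coded 0 matches anything), found
    by exhaustive enumeration of all intervals."""
    k, m = haps.shape
    best = (anchor, anchor)
    for l in range(m):
        for r in range(l, m):
            if not (l <= anchor <= r):
                continue
            ok = all(
                len({h[j] for h in haps if h[j] != 0}) <= 1 for j in range(l, r + 1)
            )
            if ok and (r - l) > (best[1] - best[0]):
                best = (l, r)
    return best
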