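"""Unvectorized reference implementation of the generative model.

A deliberately naive, scalar-loop transcription of the simulation recipe,
consuming the random stream in the same documented order as the production
path.  Used as an independent oracle for small instances.
"""

import math

import numpy as np


def straight_line_simulate(params):
    """Per-gene, per-sample scalar transcription of the simulator."""
    rng = np.random.default_rng(params.rseed)
    n, m1, m2 = params.n, params.m1, params.m2

    z = [rng.beta(params.shape1, params.shape2) for _ in range(n)]
    zbar = [params.lb + params.ub * zi for zi in z]
    alpha = [params.lambda1 * math.exp(-params.lambda1 * zb) for zb in zbar]

    y = []
    for i in range(n):
        lo = (1.0 - alpha[i]) * zbar[i]
        hi = (1.0 + alpha[i]) * zbar[i]
        y.append([lo + (hi - lo) * rng.random() for _ in range(m1 + m2 + 1)])

    u_de = [rng.random() for _ in range(n)]
    de_idx = [i for i in range(n) if u_de[i] < params.pde]
    status = [0] * n
    for i in de_idx:
        status[i] = 1 if rng.random() > params.sym else -1
    mu = {i: params.mu_de_min + rng.exponential(1.0 / params.lambda2)
          for i in de_idx}
    for i in de_idx:
        for j in range(m2):
            y[i][m1 + 1 + j] += status[i] * rng.normal(mu[i], params.sd_de)

    if params.sd_n > 0:
        for i in range(n):
            for j in range(m1 + m2 + 1):
                y[i][j] += rng.normal(0.0, params.sd_n)

    ybar = np.array(y)
    reference = ybar[:, 0]
    if params.ratio:
        x = ybar[:, 1:] - reference[:, None]
    else:
        x = ybar[:, 1:]
    return x, reference, np.array(status)
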