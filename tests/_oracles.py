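"""Independent oracles used by the tests.

These deliberately avoid the package's own computational paths: the grid
quadrature integrates the mixing posterior by brute force over a simplex
lattice, and the hand-expanded log density below mirrors the model formula
term by term with scalar arithmetic.
"""
from __future__ import annotations

import itertools
import math

import numpy as np

from trophlink import log_posterior


def simplex_grid(k: int, step: float) -> np.ndarray:
    """All lattice points with coordinates that are multiples of ``step``
    and sum to one."""
    m = int(round(1.0 / step))
    pts = []
    for c in itertools.product(range(m + 1), repeat=k - 1):
        rest = m - sum(c)
        if rest >= 0:
            pts.append(list(c) + [rest])
    return np.asarray(pts, dtype=float) / m


def grid_posterior_means(problem, step: float) -> np.ndarray:
    """Proportion posterior means by dense quadrature of log_posterior."""
    pts = simplex_grid(problem.n_sources, step)
    logs = np.array([log_posterior(p, problem) for p in pts])
    w = np.exp(logs - logs.max())
    w /= w.sum()
    return w @ pts


def hand_log_density(p1, x_c, x_n, src, prior_alpha=(1.0, 1.0)):
    """Two-source, one-individual mixing log density written out by hand.

    ``src`` is a list of two dicts with keys mu_c, sd_c, mu_n, sd_n, tef_c,
    tef_sd_c, tef_n, tef_sd_n.
    """
    p2 = 1.0 - p1
    m_c = p1 * (src[0]["mu_c"] + src[0]["tef_c"]) + p2 * (src[1]["mu_c"] + src[1]["tef_c"])
    m_n = p1 * (src[0]["mu_n"] + src[0]["tef_n"]) + p2 * (src[1]["mu_n"] + src[1]["tef_n"])
    v_c = p1**2 * (src[0]["sd_c"] ** 2 + src[0]["tef_sd_c"] ** 2) + p2**2 * (
        src[1]["sd_c"] ** 2 + src[1]["tef_sd_c"] ** 2
    )
    v_n = p1**2 * (src[0]["sd_n"] ** 2 + src[0]["tef_sd_n"] ** 2) + p2**2 * (
        src[1]["sd_n"] ** 2 + src[1]["tef_sd_n"] ** 2
    )
    ll = -0.5 * (math.log(2 * math.pi * v_c) + (x_c - m_c) ** 2 / v_c)
    ll += -0.5 * (math.log(2 * math.pi * v_n) + (x_n - m_n) ** 2 / v_n)
    a1, a2 = prior_alpha
    # Dirichlet(a1, a2) log pdf incl. normalising constant
    ll += (
        math.lgamma(a1 + a2)
        - math.lgamma(a1)
        - math.lgamma(a2)
        + (a1 - 1.0) * math.log(p1)
        + (a2 - 1.0) * math.log(p2)
    )
    return ll
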