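"""Independent oracles used by the test suite.

These are deliberately naive computations — a discrete Wright-Fisher
transition matrix solved with its fundamental matrix, and brute-force
pairwise diversity — kept free of any code path they are used to check.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def wf_transition_matrix(two_N: int, gamma: float, h: float = 0.5) -> np.ndarray:
    """Discrete WF transition matrix over allele counts 0..2N.

    Deterministic selection (``s = gamma / 2N``, dominance ``h``) followed by
    binomial sampling of 2N allele copies.
    """
    s = gamma / two_N
    j = np.arange(two_N + 1)
    x = j / two_N
    w_bar = x**2 * (1 + s) + 2 * x * (1 - x) * (1 + h * s) + (1 - x) ** 2
    x_prime = (x**2 * (1 + s) + x * (1 - x) * (1 + h * s)) / w_bar
    P = np.empty((two_N + 1, two_N + 1))
    for row, xp in enumerate(x_prime):
        P[row] = stats.binom.pmf(j, two_N, xp)
    return P


def wf_sojourn_times(two_N: int, gamma: float, h: float = 0.5) -> np.ndarray:
    """Expected generations spent at each count 1..2N-1 by a new mutation.

    Fundamental-matrix absorption-time computation: ``t = e_1 (I - Q)^-1``
    where Q is the transition matrix restricted to transient states.
    """
    P = wf_transition_matrix(two_N, gamma, h)
    Q = P[1:-1, 1:-1]
    n_t = np.eye(two_N - 1) - Q
    t = np.linalg.solve(n_t.T, np.eye(two_N - 1)[:, 0])  # row of (I-Q)^-1
    return t


def wf_fixation_prob(two_N: int, gamma: float, h: float = 0.5) -> float:
    """Absorption probability at fixation for a single new copy."""
    P = wf_transition_matrix(two_N, gamma, h)
    Q = P[1:-1, 1:-1]
    R_fix = P[1:-1, -1]
    absorb = np.linalg.solve(np.eye(two_N - 1) - Q, R_fix)
    return float(absorb[0])


def wf_expected_sample_sfs(two_N: int, gamma: float, n_chrom: int,
                           h: float = 0.5) -> np.ndarray:
    """Expected sample uSFS per unit of theta*L.

    At equilibrium the expected count in class i is
    ``2N*mu*L * sum_j t_j * Binom(i; n, j/2N)``; dividing by
    ``theta*L = 4N*mu*L`` leaves the factor 1/2 used here.
    """
    t = wf_sojourn_times(two_N, gamma, h)
    x = np.arange(1, two_N) / two_N
    out = np.empty(n_chrom - 1)
    for i in range(1, n_chrom):
        out[i - 1] = 0.5 * np.sum(t * stats.binom.pmf(i, n_chrom, x))
    return out


def brute_force_pi(G: np.ndarray) -> float:
    """Mean pairwise difference count over all distinct genome pairs."""
    n = G.shape[0]
    total = 0
    for a in range(n):
        for b in range(a + 1, n):
            total += int(np.sum(G[a] != G[b]))
    return total / (n * (n - 1) / 2)
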