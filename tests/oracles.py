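"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package's simulation path.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.linalg import expm


def master_equation_mean(n_nodes: int,
                         pairs: list[tuple[int, int]],
                         init_present: list[bool],
                         a0: np.ndarray,
                         d_intra: float,
                         k_fis: float,
                         k_fus: float,
                         t: float) -> np.ndarray:
    """Exact E[a(t)] for the joint (topology, tracer) process.

    The edge set is a CTMC over all 2^E configurations (each edge flips
    independently: present -> absent at k_fis, absent -> present at
    k_fus); conditional on the topology path the tracer obeys the
    linear mixing ODE.  The vector m_c(t) = E[a(t) 1{config = c}]
    satisfies a linear ODE of dimension n * 2^E, solved here with a
    dense matrix exponential.
    """
    n_e = len(pairs)
    n_c = 2 ** n_e
    dim = n_nodes * n_c
    gen = np.zeros((dim, dim))

    def lap(config: int) -> np.ndarray:
        L = np.zeros((n_nodes, n_nodes))
        for e, (i, j) in enumerate(pairs):
            if config >> e & 1:
                L[i, i] += 1
                L[j, j] += 1
                L[i, j] -= 1
                L[j, i] -= 1
        return L

    for c in range(n_c):
        block = slice(c * n_nodes, (c + 1) * n_nodes)
        gen[block, block] -= d_intra * lap(c)
        out_rate = 0.0
        for e in range(n_e):
            rate = k_fis if (c >> e & 1) else k_fus
            out_rate += rate
            c2 = c ^ (1 << e)
            block2 = slice(c2 * n_nodes, (c2 + 1) * n_nodes)
            # transition c -> c2 moves mass between blocks
            gen[block2, block] += rate * np.eye(n_nodes)
        gen[block, block] -= out_rate * np.eye(n_nodes)

    c0 = sum(1 << e for e, on in enumerate(init_present) if on)
    m0 = np.zeros(dim)
    m0[c0 * n_nodes:(c0 + 1) * n_nodes] = a0
    m = expm(gen * t) @ m0
    return m.reshape(n_c, n_nodes).sum(axis=0)


def binomial_se(p: float, n: int) -> float:
    return float(np.sqrt(p * (1 - p) / n))


def students_t_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook equal-variance two-sample t test (two-sided)."""
    from scipy.stats import t as tdist

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = x.size, y.size
    sp2 = (((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1))
           / (nx + ny - 2))
    tval = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
    return float(2 * tdist.sf(abs(tval), nx + ny - 2))


def full_lattice_edge_count(n_long: int, n_trans: int) -> int:
    """Count lattice-neighbor pairs by enumeration."""
    count = 0
    for r, c in itertools.product(range(n_trans), range(n_long)):
        if c + 1 < n_long:
            count += 1
        if r + 1 < n_trans:
            count += 1
    return count
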