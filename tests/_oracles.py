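"""Brute-force oracles, independent of the LP code paths.

The steady-state flux space S = {v | Nv = 0, lb <= v <= ub} is a bounded
polytope; a linear functional vanishes on S iff it vanishes at every vertex,
and two functionals are proportional on S iff they are proportional (with a
common ratio) at every vertex. Vertices are enumerated by fixing n - rank(N)
flux bounds at their lower or upper value and solving the resulting square
system — feasible only for tiny networks, which is the point: the oracle
shares no code with the LP engine it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

TOL = 1e-7


def polytope_vertices(N: np.ndarray, lb: np.ndarray, ub: np.ndarray) -> np.ndarray:
    """All vertices of {v | Nv = 0, lb <= v <= ub} (tiny systems only)."""
    m, n = N.shape
    rank = np.linalg.matrix_rank(N)
    k = n - rank
    verts = []
    for idx in itertools.combinations(range(n), k):
        for values in itertools.product(*[(lb[j], ub[j]) for j in idx]):
            rows = [N]
            rhs = [np.zeros(m)]
            for j, val in zip(idx, values):
                e = np.zeros(n)
                e[j] = 1.0
                rows.append(e.reshape(1, -1))
                rhs.append([val])
            A = np.vstack(rows)
            b = np.concatenate(rhs)
            if np.linalg.matrix_rank(A) < n:
                continue
            v, *_ = np.linalg.lstsq(A, b, rcond=None)
            if np.max(np.abs(A @ v - b)) > TOL:
                continue
            if np.any(v < lb - TOL) or np.any(v > ub + TOL):
                continue
            verts.append(np.clip(v, lb, ub))
    if not verts:
        return np.empty((0, n))
    V = np.array(verts)
    # deduplicate
    _, keep = np.unique(np.round(V, 6), axis=0, return_index=True)
    return V[sorted(keep)]


def balanced_by_vertices(activity_row: np.ndarray, vertices: np.ndarray) -> bool:
    if vertices.size == 0:
        return True
    return bool(np.max(np.abs(vertices @ activity_row)) <= TOL)


def concordant_by_vertices(
    row_i: np.ndarray, row_j: np.ndarray, vertices: np.ndarray
) -> bool:
    """True iff activities are proportional with one nonzero ratio."""
    ai = vertices @ row_i
    aj = vertices @ row_j
    nz = np.abs(ai) > TOL
    if not nz.any():  # i balanced; concordance is defined on non-balanced pairs
        return False
    gammas = aj[nz] / ai[nz]
    gamma = gammas[0]
    if abs(gamma) <= TOL:
        return False
    if np.max(np.abs(gammas - gamma)) > TOL:
        return False
    # wherever the reference activity vanishes the other must too
    return bool(np.all(np.abs(aj[~nz]) <= TOL * max(1.0, abs(gamma))))
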