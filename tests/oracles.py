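"""Independent brute-force oracles for the LP and iMAT solvers.

These deliberately avoid the package's solver path: the FBA oracle
enumerates the vertices of the flux polytope directly from linear algebra,
and the iMAT oracle enumerates every binary assignment and checks each with
a plain feasibility LP.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
from scipy.optimize import linprog


def brute_force_fba_max(S, lb, ub, c, tol=1e-7):
    """LP maximum by explicit vertex enumeration of {S v = 0, lb <= v <= ub}.

    A vertex of the bounded polytope activates at least d = n - rank(S) box
    constraints whose unit rows complete S to full column rank. Assumes the
    polytope is non-empty (0 must be feasible for the generated networks).
    """
    S = np.asarray(S, dtype=float)
    lb, ub, c = map(np.asarray, (lb, ub, c))
    n = S.shape[1]
    rank = np.linalg.matrix_rank(S) if S.size else 0
    d = n - rank
    best = None
    if d == 0:
        v = np.zeros(n)
        if np.all(v >= lb - tol) and np.all(v <= ub + tol):
            best = float(c @ v)
        return best
    for J in combinations(range(n), d):
        for pattern in product((0, 1), repeat=d):
            A = np.vstack([S] + [np.eye(n)[j] for j in J])
            b = np.concatenate(
                [np.zeros(S.shape[0]),
                 [ub[j] if p else lb[j] for j, p in zip(J, pattern)]]
            )
            if np.linalg.matrix_rank(A) < n:
                continue
            v, *_ = np.linalg.lstsq(A, b, rcond=None)
            if np.max(np.abs(A @ v - b)) > tol:
                continue
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            val = float(c @ v)
            if best is None or val > best:
                best = val
    return best


def brute_force_imat_objective(S, lb, ub, high_idx, low_idx, eps):
    """iMAT optimum by exhaustive enumeration of reaction activity states.

    Each high reaction is forced inactive / forward-active (v >= eps) /
    reverse-active (v <= -eps); each low reaction is free or silenced
    (v = 0). Every assignment is checked with a feasibility LP; the
    objective counts active high and silenced low reactions.
    """
    S = np.asarray(S, dtype=float)
    lb, ub = np.asarray(lb, float), np.asarray(ub, float)
    n = S.shape[1]
    best = -1
    for high_states in product((0, 1, 2), repeat=len(high_idx)):
        for low_states in product((0, 1), repeat=len(low_idx)):
            lo, hi = lb.copy(), ub.copy()
            ok = True
            for j, state in zip(high_idx, high_states):
                if state == 1:
                    lo[j] = max(lo[j], eps)
                elif state == 2:
                    hi[j] = min(hi[j], -eps)
                if lo[j] > hi[j]:
                    ok = False
            for j, state in zip(low_idx, low_states):
                if state:
                    lo[j] = max(lo[j], 0.0)
                    hi[j] = min(hi[j], 0.0)
                    if lo[j] > hi[j]:
                        ok = False
            if not ok:
                continue
            score = sum(1 for s in high_states if s) + sum(low_states)
            if score <= best:
                continue
            res = linprog(
                np.zeros(n), A_eq=S, b_eq=np.zeros(S.shape[0]),
                bounds=list(zip(lo, hi)), method="highs",
            )
            if res.status == 0:
                best = score
    return best


def random_network(rng, max_reactions=6, max_metabolites=4):
    """A random small stoichiometric network with 0 in the flux box.

    Integer coefficients in [-2, 2], lower bounds in {0, -5}, upper bounds
    in [2, 10]; the zero flux vector is always feasible, so the polytope is
    non-empty and bounded.
    """
    n = int(rng.integers(2, max_reactions + 1))
    m = int(rng.integers(1, max_metabolites + 1))
    while True:
        S = rng.integers(-2, 3, size=(m, n)).astype(float)
        if np.any(S):
            break
    lb = np.where(rng.random(n) < 0.4, -5.0, 0.0)
    ub = rng.integers(2, 11, size=n).astype(float)
    c = rng.integers(0, 3, size=n).astype(float)
    if not np.any(c):
        c[int(rng.integers(0, n))] = 1.0
    return S, lb, ub, c
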