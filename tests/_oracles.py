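"""Independent oracles used by the test suite.

These deliberately re-derive results by brute force or quadrature, sharing
no code with the implementation paths they check.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
from scipy.integrate import quad


def vertex_enumeration_lp(S: np.ndarray, lb, ub, c) -> float:
    """Maximise c.v over {S v = 0, lb <= v <= ub} by vertex enumeration.

    Every vertex of the polytope has at least d = n - rank(S) coordinates at
    a bound; enumerate all such activations, solve the equality system for
    the remaining coordinates, and keep feasible points.  Only for tiny
    problems (n <= ~8).
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    c = np.asarray(c, dtype=float)
    n = S.shape[1]
    rank = np.linalg.matrix_rank(S)
    d = n - rank
    best = -np.inf
    tol = 1e-8
    for fixed in combinations(range(n), d):
        free = [i for i in range(n) if i not in fixed]
        for bounds_choice in product(*[(lb[i], ub[i]) for i in fixed]):
            v = np.zeros(n)
            v[list(fixed)] = bounds_choice
            if free:
                A = S[:, free]
                b = -S[:, list(fixed)] @ np.array(bounds_choice)
                sol, *_ = np.linalg.lstsq(A, b, rcond=None)
                v[free] = sol
            if np.max(np.abs(S @ v)) > tol:
                continue
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            best = max(best, float(c @ v))
    return best


def enumerate_alignments(a: str, b: str):
    """Yield all global alignments of a and b as (aligned_a, aligned_b)."""
    if not a and not b:
        yield "", ""
        return
    if a and b:
        for x, y in enumerate_alignments(a[1:], b[1:]):
            yield a[0] + x, b[0] + y
    if a:
        for x, y in enumerate_alignments(a[1:], b):
            yield a[0] + x, "-" + y
    if b:
        for x, y in enumerate_alignments(a, b[1:]):
            yield "-" + x, b[0] + y


def score_alignment(
    aligned_a: str, aligned_b: str, matrix, gap_open: float, gap_extend: float
) -> float:
    """Score one alignment: substitution score per match column, and each
    gap run of length L (terminal runs included) costs gap_open +
    L*gap_extend."""
    score = 0.0
    # substitution columns
    for x, y in zip(aligned_a, aligned_b):
        if x != "-" and y != "-":
            score += matrix[x, y]
    # gap runs in either row
    for row in (aligned_a, aligned_b):
        run = 0
        for ch in row:
            if ch == "-":
                run += 1
            else:
                if run:
                    score -= gap_open + run * gap_extend
                run = 0
        if run:
            score -= gap_open + run * gap_extend
    return score


def brute_force_align_score(
    a: str, b: str, matrix, gap_open: float = 11.0, gap_extend: float = 1.0
) -> float:
    """Optimal global affine-gap score by exhaustive enumeration."""
    best = -np.inf
    for xa, xb in enumerate_alignments(a, b):
        # adjacent gap-vs-gap columns never help; skip alignments with them
        if any(p == "-" and q == "-" for p, q in zip(xa, xb)):
            continue
        best = max(best, score_alignment(xa, xb, matrix, gap_open, gap_extend))
    return best


def quadrature_delta_r_g(
    drH_ref: float, drS_ref: float, cp_coeffs: tuple[float, float, float],
    T_ref: float, T: float,
) -> float:
    """Gibbs energy of reaction at T by numerical quadrature of the heat
    capacity integrals (Cp in J/(mol K); energies kJ/mol; entropy J/(mol K))."""
    a, b, c = cp_coeffs

    def cp(t):
        return a + b * t + c * t * t

    int_cp, _ = quad(cp, T_ref, T, limit=200)
    int_cp_t, _ = quad(lambda t: cp(t) / t, T_ref, T, limit=200)
    h = drH_ref + int_cp / 1000.0
    s = drS_ref + int_cp_t
    return h - T * s / 1000.0
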