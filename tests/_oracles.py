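"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths under test: the LP oracle enumerates
candidate vertices of the bounded polyhedron directly, and the alignment
oracle is a plain quadratic-time Gotoh dynamic program.
"""

from __future__ import annotations

import itertools

import numpy as np

_FEAS_TOL = 1e-7


def lp_oracle_max(c, A_eq, b_eq, bounds):
    """Maximize ``c·x`` s.t. ``A_eq x = b_eq`` and box bounds, by enumerating
    candidate vertices (every choice of ``n − rank`` variables fixed at a
    bound, solving the square equality system for the rest).

    All bounds must be finite.  Returns the best objective value, or None if
    no feasible candidate exists.  Only suitable for tiny problems.
    """
    A = np.asarray(A_eq, dtype=float)
    b = np.asarray(b_eq, dtype=float)
    c = np.asarray(c, dtype=float)
    lb = np.array([lo for lo, _ in bounds], dtype=float)
    ub = np.array([hi for _, hi in bounds], dtype=float)
    if not (np.all(np.isfinite(lb)) and np.all(np.isfinite(ub))):
        raise ValueError("oracle requires finite bounds")
    n = A.shape[1]
    rank = np.linalg.matrix_rank(A)
    n_fixed = n - rank
    best = None

    for fixed in itertools.combinations(range(n), n_fixed):
        free = [j for j in range(n) if j not in fixed]
        A_free = A[:, free]
        A_fixed = A[:, list(fixed)]
        for pattern in itertools.product((0, 1), repeat=n_fixed):
            x_fixed = np.array(
                [lb[j] if side == 0 else ub[j] for j, side in zip(fixed, pattern)]
            )
            rhs = b - A_fixed @ x_fixed
            sol, *_ = np.linalg.lstsq(A_free, rhs, rcond=None)
            x = np.empty(n)
            x[list(fixed)] = x_fixed
            x[free] = sol
            if np.max(np.abs(A @ x - b), initial=0.0) > _FEAS_TOL:
                continue
            if np.any(x < lb - _FEAS_TOL) or np.any(x > ub + _FEAS_TOL):
                continue
            val = float(c @ x)
            if best is None or val > best:
                best = val
    return best


def _model_lp(model, objective):
    """Equality-form LP data (c, S, 0, bounds) for a MetabolicModel."""
    rxn_ids = list(model.reactions)
    met_index = {m: i for i, m in enumerate(model.metabolites)}
    S = np.zeros((len(met_index), len(rxn_ids)))
    bounds = []
    c = np.zeros(len(rxn_ids))
    for j, rid in enumerate(rxn_ids):
        rxn = model.reactions[rid]
        for met, coef in rxn.stoichiometry.items():
            S[met_index[met], j] = coef
        bounds.append((rxn.lower_bound, rxn.upper_bound))
        c[j] = objective.get(rid, 0.0)
    return c, S, np.zeros(S.shape[0]), bounds, rxn_ids


def oracle_fba(model, objective):
    """Optimal objective value of FBA on *model*, by vertex enumeration."""
    c, S, b, bounds, _ = _model_lp(model, objective)
    return lp_oracle_max(c, S, b, bounds)


def oracle_fair_split(model, bio_a, bio_b, joint_optimum, big=1e4):
    """Max-min growth split on the optimal face, by vertex enumeration.

    Builds the equality-form epigraph LP: variables (v, t, s_a, s_b) with
    ``v_a − t − s_a = 0``, ``v_b − t − s_b = 0`` (slacks ≥ 0 encode t ≤ v),
    ``v_a + v_b = joint optimum``, maximizing t.  Returns the max-min value.
    """
    _, S, b, bounds, rxn_ids = _model_lp(model, {})
    n = len(rxn_ids)
    ia, ib = rxn_ids.index(bio_a), rxn_ids.index(bio_b)
    m = S.shape[0]
    A = np.zeros((m + 3, n + 3))
    A[:m, :n] = S
    A[m, ia], A[m, n], A[m, n + 1] = 1.0, -1.0, -1.0
    A[m + 1, ib], A[m + 1, n], A[m + 1, n + 2] = 1.0, -1.0, -1.0
    A[m + 2, ia] = A[m + 2, ib] = 1.0
    b_full = np.concatenate([b, [0.0, 0.0, joint_optimum]])
    bounds_full = bounds + [(0.0, big), (0.0, big), (0.0, big)]
    c = np.zeros(n + 3)
    c[n] = 1.0
    return lp_oracle_max(c, A, b_full, bounds_full)


# ---------------------------------------------------------------------------
# Local alignment oracle
# ---------------------------------------------------------------------------

_ACGT = set("ACGT")


def sw_oracle_score(a: str, b: str, match=2.0, mismatch=-3.0, open_=-5.0, ext=-2.0):
    """Best local-alignment score by the O(nm) Gotoh dynamic program.

    Affine gaps: the first residue of a gap scores *open_*, each further
    residue *ext* (so a length-k gap scores open_ + (k−1)·ext).  Ambiguity
    characters never score as matches.
    """
    a = a.upper().replace("U", "T")
    b = b.upper().replace("U", "T")
    n, m = len(a), len(b)
    neg = float("-inf")
    best = 0.0
    H_prev = [0.0] * (m + 1)
    F_prev = [neg] * (m + 1)
    for i in range(1, n + 1):
        H_cur = [0.0] * (m + 1)
        F_cur = [neg] * (m + 1)
        E = neg
        ai = a[i - 1]
        for j in range(1, m + 1):
            E = max(H_cur[j - 1] + open_, E + ext)
            F_cur[j] = max(H_prev[j] + open_, F_prev[j] + ext)
            s = match if (ai == b[j - 1] and ai in _ACGT) else mismatch
            h = max(0.0, H_prev[j - 1] + s, E, F_cur[j])
            H_cur[j] = h
            if h > best:
                best = h
        H_prev, F_prev = H_cur, F_cur
    return best
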