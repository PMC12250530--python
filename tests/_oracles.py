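"""Independent oracles used by the test suite.

These deliberately share no code with the package under test:

* ``enumerate_vertices`` / ``fva_oracle`` / ``fba_oracle`` solve tiny flux LPs
  by brute-force vertex enumeration of the polytope {Sv=0, lb<=v<=ub} (every
  linear optimum over a bounded nonempty polytope is attained at a vertex);
* ``naive_ko_matrix`` recomputes the knockout effect matrix with one fresh LP
  per (metabolite, reaction) cell, reading consumption directions straight
  off the stoichiometry;
* ``two_sample_t_oracle`` is the closed-form pooled two-sample t-test;
* ``random_lp_model`` generates small random stoichiometric models with
  finite bounds for the LP-equivalence checks.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy.optimize import linprog
from scipy import stats

from fluxscreen.model_io import MetabolicModel, Metabolite, Reaction


def enumerate_vertices(S, lb, ub, tol=1e-8):
    """All vertices of {v : Sv = 0, lb <= v <= ub}.

    Enumerates every assignment of each variable to {lb, ub, free}; an
    assignment pins a unique point iff the free columns of S have full column
    rank. Feasible unique solutions are vertices, and every vertex arises
    from fixing (a superset of) its tight bounds this way.
    """
    S = np.asarray(S, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    m, n = S.shape
    verts = []
    for assign in product((0, 1, 2), repeat=n):  # 0=lb, 1=ub, 2=free
        fixed = [j for j in range(n) if assign[j] != 2]
        free = [j for j in range(n) if assign[j] == 2]
        v = np.zeros(n)
        for j in fixed:
            v[j] = lb[j] if assign[j] == 0 else ub[j]
        if free:
            A = S[:, free]
            if np.linalg.matrix_rank(A) < len(free):
                continue  # not uniquely pinned; vertex found via another assignment
            b = -S[:, fixed] @ v[fixed] if fixed else np.zeros(m)
            sol, *_ = np.linalg.lstsq(A, b, rcond=None)
            v[free] = sol
        if not np.allclose(S @ v, 0.0, atol=1e-7):
            continue
        if np.any(v < lb - tol) or np.any(v > ub + tol):
            continue
        verts.append(np.clip(v, lb, ub))
    if not verts:
        return np.empty((0, n))
    verts = np.array(verts)
    # deduplicate
    keep = []
    for v in verts:
        if not any(np.allclose(v, w, atol=1e-7) for w in keep):
            keep.append(v)
    return np.array(keep)


def fva_oracle(S, lb, ub):
    """(min, max) flux per reaction from vertex enumeration; None if infeasible."""
    verts = enumerate_vertices(S, lb, ub)
    if verts.size == 0:
        return None
    return verts.min(axis=0), verts.max(axis=0)


def fba_oracle(S, lb, ub, j, sense="max"):
    """Optimal flux of reaction j from vertex enumeration; None if infeasible."""
    verts = enumerate_vertices(S, lb, ub)
    if verts.size == 0:
        return None
    col = verts[:, j]
    return float(col.max() if sense == "max" else col.min())


def random_lp_model(seed, n_mets=4, n_rxns=7):
    """Small random stoichiometric model with finite bounds straddling zero."""
    rng = np.random.default_rng(seed)
    mets = [Metabolite(id=f"M{i}[c]", name=f"M{i}", compartment="c") for i in range(n_mets)]
    rxns = []
    for j in range(n_rxns):
        size = int(rng.integers(1, min(3, n_mets) + 1))
        members = rng.choice(n_mets, size=size, replace=False)
        coefs = rng.choice([-2, -1, 1, 2], size=size)
        stoich = {f"M{i}[c]": float(c) for i, c in zip(members, coefs)}
        lo = float(np.round(rng.uniform(-5, 0), 1))
        hi = float(np.round(rng.uniform(0, 5), 1))
        rxns.append(Reaction(id=f"R{j}", stoichiometry=stoich, lb=lo, ub=hi))
    model = MetabolicModel(metabolites=mets, reactions=rxns).validate()
    return model


def naive_ko_matrix(model, bounds, tol=1e-6, abs_floor=1e-9):
    """Independent M(KO): fresh LP per cell, own bound bookkeeping."""
    S, met_ids, rxn_ids = model.stoichiometric_matrix()
    bmap = bounds.bounds if hasattr(bounds, "bounds") else dict(bounds)
    base = np.array([bmap.get(r, (model.reactions[j].lb, model.reactions[j].ub))
                     for j, r in enumerate(rxn_ids)])
    exchange = np.array([len(r.stoichiometry) == 1 for r in model.reactions])

    def solve_max(lbs, ubs, j):
        c = np.zeros(len(rxn_ids))
        c[j] = -1.0
        res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                      bounds=list(zip(lbs, ubs)), method="highs")
        if res.status != 0:
            return None
        return float(res.x[j])

    wt = np.array([solve_max(base[:, 0], base[:, 1], j) for j in range(len(rxn_ids))])
    M = np.zeros((len(met_ids), len(rxn_ids)), dtype=int)
    for i, met in enumerate(met_ids):
        lbs, ubs = base[:, 0].copy(), base[:, 1].copy()
        for j in range(len(rxn_ids)):
            if exchange[j]:
                continue
            coef = S[i, j]
            if coef < 0:
                ubs[j] = min(ubs[j], 0.0)
                lbs[j] = min(lbs[j], ubs[j])
            elif coef > 0:
                lbs[j] = max(lbs[j], 0.0)
                ubs[j] = max(ubs[j], lbs[j])
        for j in range(len(rxn_ids)):
            ko = solve_max(lbs, ubs, j)
            if ko is None:
                M[i, j] = -1 if wt[j] is not None and wt[j] > abs_floor else 0
                continue
            thresh = max(tol * abs(wt[j]), abs_floor)
            if ko < wt[j] - thresh:
                M[i, j] = -1
            elif ko > wt[j] + thresh:
                M[i, j] = 1
    return M, met_ids, rxn_ids


def two_sample_t_oracle(x, y):
    """Ordinary pooled two-sample t and two-sided p (closed form)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    d = n1 + n2 - 2
    s2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / d
    t = (x.mean() - y.mean()) / np.sqrt(s2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), d)
    return t, p
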