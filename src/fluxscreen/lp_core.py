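"""Linear-programming engine: FBA, FVA and metabolite knockout.

All solves go through scipy's HiGHS backend with deterministic settings; the
feasible set is always {v : S v = 0, lb <= v <= ub}. FVA here carries no
optimality-fraction constraint on any other objective — each reaction is
simply minimized and maximized over the same polytope. Correctness is defined
by these naive per-LP semantics; any warm-start/factorization-sharing strategy
a faster implementation might use is an optimization, not a contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .errors import InfeasibleModelError, ParameterError
from .gpmm_bounds import BoundSet
from .model_io import MetabolicModel, identify_exchanges

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"

_STATUS = {0: OPTIMAL, 2: INFEASIBLE, 3: UNBOUNDED}

#: default relative tolerance for knockout effect calls
KO_TOL = 1e-6
#: absolute floor below which wild-type maxima count as zero
KO_ABS_FLOOR = 1e-9


@dataclass
class _LPProblem:
    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    rxn_ids: list[str]
    met_ids: list[str]

    def index(self, rxn_id: str) -> int:
        try:
            return self.rxn_ids.index(rxn_id)
        except ValueError:
            raise KeyError(f"unknown reaction {rxn_id!r}") from None


def _build(model: MetabolicModel, bounds) -> _LPProblem:
    S, met_ids, rxn_ids = model.stoichiometric_matrix()
    bmap = bounds.bounds if isinstance(bounds, BoundSet) else dict(bounds)
    lb = np.empty(len(rxn_ids))
    ub = np.empty(len(rxn_ids))
    for j, rxn in enumerate(model.reactions):
        lo, hi = bmap.get(rxn.id, (rxn.lb, rxn.ub))
        lb[j], ub[j] = lo, hi
    return _LPProblem(S=S, lb=lb, ub=ub, rxn_ids=rxn_ids, met_ids=met_ids)


def _solve(prob: _LPProblem, c: np.ndarray):
    res = linprog(
        c,
        A_eq=prob.S,
        b_eq=np.zeros(prob.S.shape[0]),
        bounds=list(zip(prob.lb, prob.ub)),
        method="highs",
    )
    status = _STATUS.get(res.status, INFEASIBLE)
    return res, status


def fba(model: MetabolicModel, bounds, objective: str, sense: str = "max"):
    """Flux balance analysis: optimize one reaction's flux.

    Returns ``(objective_value, flux_series, status)``; on non-optimal status
    the value is NaN and the flux series is empty — never silently clamped.
    """
    if sense not in ("max", "min"):
        raise ParameterError(f"sense must be 'max' or 'min', got {sense!r}")
    prob = _build(model, bounds)
    j = prob.index(objective)
    c = np.zeros(len(prob.rxn_ids))
    c[j] = -1.0 if sense == "max" else 1.0
    res, status = _solve(prob, c)
    if status != OPTIMAL:
        return float("nan"), pd.Series(dtype=float), status
    value = float(res.x[j])
    return value, pd.Series(res.x, index=prob.rxn_ids), status


def _assert_feasible(model: MetabolicModel, prob: _LPProblem) -> None:
    res, status = _solve(prob, np.zeros(len(prob.rxn_ids)))
    if status == OPTIMAL:
        return
    exchanges = identify_exchanges(model)
    detail = ", ".join(
        f"{r}[{prob.lb[prob.index(r)]:g},{prob.ub[prob.index(r)]:g}]"
        for r in exchanges[:20]
    )
    raise InfeasibleModelError(
        f"model has no feasible flux distribution (status {status}); "
        f"exchange bounds: {detail}"
    )


def fva(
    model: MetabolicModel,
    bounds,
    reactions: Sequence[str] | None = None,
    direction: str = "both",
) -> pd.DataFrame:
    """Per-reaction (min, max) attainable flux over the shared feasible set.

    ``direction="max"`` (or ``"min"``) solves only one LP per reaction and
    leaves the other column NaN — an optimization for callers that consume a
    single side, with semantics per-LP identical to the full run.
    """
    if direction not in ("both", "min", "max"):
        raise ParameterError(f"direction must be both/min/max, got {direction!r}")
    prob = _build(model, bounds)
    _assert_feasible(model, prob)
    if reactions is None:
        reactions = prob.rxn_ids
    n = len(prob.rxn_ids)
    out = np.full((len(reactions), 2), np.nan)
    for i, rxn in enumerate(reactions):
        j = prob.index(rxn)
        if prob.lb[j] == prob.ub[j]:
            out[i] = (prob.lb[j], prob.ub[j])
            continue
        c = np.zeros(n)
        vmin = vmax = float("nan")
        if direction in ("both", "min"):
            c[j] = 1.0
            res_min, st_min = _solve(prob, c)
            vmin = float(res_min.x[j]) if st_min == OPTIMAL else float("nan")
        if direction in ("both", "max"):
            c[j] = -1.0
            res_max, st_max = _solve(prob, c)
            vmax = float(res_max.x[j]) if st_max == OPTIMAL else float("nan")
        if np.isfinite(vmin) and np.isfinite(vmax) and vmin > vmax:
            vmin = vmax = 0.5 * (vmin + vmax)  # solver noise on degenerate LPs
        out[i] = (vmin, vmax)
    return pd.DataFrame(out, index=list(reactions), columns=["min", "max"])


def flux_matrix(
    model: MetabolicModel,
    bound_sets: Iterable[BoundSet],
    summary: str = "max",
) -> pd.DataFrame:
    """Reactions x samples flux summary from per-sample FVA.

    ``summary="max"`` reports each reaction's FVA maximum (capacity-like, the
    default); ``"mid"`` reports the midpoint of the FVA interval. The chosen
    provenance is recorded in ``DataFrame.attrs["provenance"]``.
    """
    if summary not in ("max", "mid"):
        raise ParameterError(f"summary must be 'max' or 'mid', got {summary!r}")
    cols = {}
    for bs in bound_sets:
        if summary == "max":
            cols[bs.sample_id] = fva(model, bs, direction="max")["max"]
        else:
            ranges = fva(model, bs)
            cols[bs.sample_id] = 0.5 * (ranges["min"] + ranges["max"])
    out = pd.DataFrame(cols)
    out.attrs["provenance"] = f"fva_{summary}"
    return out


def knockout_metabolite(model: MetabolicModel, bounds, metabolite_id: str):
    """Block consumption of one metabolite; returns a new bounds mapping.

    For every non-exchange reaction touching the metabolite, the direction
    that consumes it is closed: forward consumers (negative coefficient) get
    ub = 0, reverse consumers (positive coefficient, lb < 0) get lb = 0.
    Exchange reactions are untouched. Production is deliberately left open —
    the knockout removes the pool's availability, not the cell's ability to
    make it.
    """
    if metabolite_id not in {m.id for m in model.metabolites}:
        raise KeyError(f"unknown metabolite {metabolite_id!r}")
    bmap = dict(bounds.bounds) if isinstance(bounds, BoundSet) else dict(bounds)
    exchanges = set(identify_exchanges(model))
    for r in model.reactions:
        coef = r.stoichiometry.get(metabolite_id)
        if coef is None or r.id in exchanges:
            continue
        lb, ub = bmap.get(r.id, (r.lb, r.ub))
        if coef < 0:  # consumed by forward flux
            ub = min(ub, 0.0)
            lb = min(lb, ub)
        elif coef > 0:  # consumed by reverse flux
            lb = max(lb, 0.0)
            ub = max(ub, lb)
        bmap[r.id] = (lb, ub)
    return bmap


def ko_effect_matrix(
    model: MetabolicModel,
    bounds,
    metabolites: Sequence[str] | None = None,
    reactions: Sequence[str] | None = None,
    tol: float = KO_TOL,
    abs_floor: float = KO_ABS_FLOOR,
    log=None,
) -> pd.DataFrame:
    """All-against-all metabolite knockout matrix M(KO).

    ``M[i, j]`` is -1 if knocking out metabolite i lowers reaction j's FVA
    maximum by more than ``tol`` (relative, with absolute floor
    ``abs_floor``), +1 if it raises it by more than that, else 0. The
    wild-type FVA is computed once and reused. An infeasible knockout model
    sets the row to -1 wherever the wild-type max exceeds the floor.
    """
    if metabolites is None:
        metabolites = [m.id for m in model.metabolites]
    if reactions is None:
        reactions = [r.id for r in model.reactions]
    wt = fva(model, bounds, reactions, direction="max")["max"].to_numpy()
    thresh = np.maximum(tol * np.abs(wt), abs_floor)
    M = np.zeros((len(metabolites), len(reactions)), dtype=int)
    for i, met in enumerate(metabolites):
        ko_bounds = knockout_metabolite(model, bounds, met)
        try:
            ko = fva(model, ko_bounds, reactions, direction="max")["max"].to_numpy()
        except InfeasibleModelError:
            if log is not None:
                log.warning("knockout of %s is infeasible; row set to -1", met)
            M[i] = np.where(wt > abs_floor, -1, 0)
            continue
        M[i] = np.where(ko < wt - thresh, -1, np.where(ko > wt + thresh, 1, 0))
    return pd.DataFrame(M, index=list(metabolites), columns=list(reactions))
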