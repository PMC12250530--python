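"""Expression-constrained Michaelis-Menten Vmax bounds and medium application.

For every sample, enzyme abundance is estimated per reaction by evaluating its
GPR over that sample's gene expression (AND=min for complexes, OR=sum for
isozymes), multiplied by the reaction's kcat and a single global calibration
constant ``scale``; the product caps the reaction's flux capacity in both
directions. This single-constant calibration is a reconstruction: it preserves
the relative structure that all downstream statistics consume without
committing to per-protein molecular weights. Likewise the OR=sum convention is
the standard isozyme reading and is documented as a reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import _gpr
from .errors import ModelValidationError, ParameterError
from .model_io import MetabolicModel, identify_exchanges

UNBOUNDED = float("inf")


@dataclass
class ExpressionMatrix:
    """Genes x samples non-negative expression values plus case/control labels."""

    values: pd.DataFrame
    labels: dict[str, str]  # sample id -> "case" | "control"

    def __post_init__(self):
        if (self.values.values < 0).any():
            raise ModelValidationError("expression matrix has negative entries")
        if self.values.columns.duplicated().any():
            raise ModelValidationError("duplicate sample ids in expression matrix")
        unknown = set(self.labels.values()) - {"case", "control"}
        if unknown:
            raise ModelValidationError(f"unknown sample labels {unknown}")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def case_samples(self) -> list[str]:
        return [s for s in self.samples if self.labels.get(s) == "case"]

    def control_samples(self) -> list[str]:
        return [s for s in self.samples if self.labels.get(s) == "control"]


@dataclass
class KinetomeTable:
    """Per-reaction turnover numbers (kcat, 1/s), with an optional default."""

    kcat: dict[str, float]
    default: float | None = None

    def __post_init__(self):
        bad = {r: k for r, k in self.kcat.items() if not k > 0}
        if bad:
            raise ModelValidationError(f"non-positive kcat values: {bad}")
        if self.default is not None and not self.default > 0:
            raise ModelValidationError(f"non-positive default kcat {self.default}")

    def get(self, rxn_id: str) -> float | None:
        return self.kcat.get(rxn_id, self.default)


@dataclass
class MediumTable:
    """Exchange-reaction uptake lower bounds (<= 0, mmol/gDW/h)."""

    uptake: dict[str, float]

    def __post_init__(self):
        bad = {r: b for r, b in self.uptake.items() if b > 0}
        if bad:
            raise ModelValidationError(f"positive uptake bounds (must be <= 0): {bad}")


@dataclass
class BoundSet:
    """Per-sample reaction bounds."""

    sample_id: str
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        for rxn, (lb, ub) in self.bounds.items():
            if lb > ub:
                raise ModelValidationError(
                    f"sample {self.sample_id!r}: reaction {rxn!r} lb {lb} > ub {ub}"
                )


def evaluate_gpr(gpr, gene_levels, missing: float = 0.0) -> float:
    """Evaluate a GPR rule (string or parsed tree) over gene abundances.

    Returns +inf for an empty rule (unconstrained reaction).
    """
    tree = _gpr.parse(gpr) if isinstance(gpr, str) or gpr is None else gpr
    return _gpr.evaluate(tree, gene_levels, missing=missing)


def compute_vmax_bounds(
    model: MetabolicModel,
    expr: ExpressionMatrix,
    kinetome: KinetomeTable,
    scale: float = 1.0,
) -> list[BoundSet]:
    """One BoundSet per sample, with Vmax = scale * kcat * GPR(expression).

    The Vmax caps the model upper bound; for reversible reactions the lower
    bound is symmetrically floored at -Vmax (enzyme capacity is
    direction-agnostic). Reactions with an empty GPR or no kcat keep their
    generic bounds. Exchange lower bounds are never touched here (the medium
    owns them).
    """
    if not scale > 0:
        raise ParameterError(f"scale must be > 0, got {scale}")
    exchanges = set(identify_exchanges(model))
    trees = {r.id: r.gpr_tree() for r in model.reactions}
    out = []
    for sample in expr.samples:
        levels = expr.values[sample].to_dict()
        bounds: dict[str, tuple[float, float]] = {}
        for r in model.reactions:
            lb, ub = r.lb, r.ub
            kcat = kinetome.get(r.id)
            tree = trees[r.id]
            if tree is not None and kcat is not None:
                vmax = scale * kcat * _gpr.evaluate(tree, levels)
                new_ub = min(ub, vmax)
                if r.id in exchanges:
                    ub = new_ub
                    lb = min(lb, ub)
                else:
                    ub = new_ub
                    if r.lb < 0:  # reversible: symmetric capacity
                        lb = max(r.lb, -vmax)
                    lb = min(lb, ub)
            bounds[r.id] = (lb, ub)
        out.append(BoundSet(sample_id=sample, bounds=bounds))
    return out


def apply_medium(
    bounds: BoundSet, model: MetabolicModel, medium: MediumTable
) -> BoundSet:
    """Set uptake bounds: listed exchanges from the medium, all others to 0.

    Secretion (upper) bounds are left unchanged.
    """
    exchanges = identify_exchanges(model)
    exchange_set = set(exchanges)
    non_exchange = [r for r in medium.uptake if r not in exchange_set]
    if non_exchange:
        raise ModelValidationError(
            f"medium names non-exchange reaction(s): {sorted(non_exchange)}"
        )
    new = dict(bounds.bounds)
    for rxn in exchanges:
        lb, ub = new[rxn]
        lb = medium.uptake.get(rxn, 0.0)
        new[rxn] = (min(lb, ub), ub)
    return BoundSet(sample_id=bounds.sample_id, bounds=new)


# ---------------------------------------------------------------------------
# TSV readers for the pipeline's tabular inputs
# ---------------------------------------------------------------------------


def read_expression_tsv(path, labels_path=None) -> ExpressionMatrix:
    """Genes x samples TSV; labels from a two-column (sample, label) TSV."""
    values = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    values = values.astype(float)
    labels: dict[str, str] = {}
    if labels_path is not None:
        lab = pd.read_csv(labels_path, sep="\t", comment="#")
        labels = dict(zip(lab.iloc[:, 0].astype(str), lab.iloc[:, 1].astype(str)))
    return ExpressionMatrix(values=values, labels=labels)


def read_kinetome_tsv(path, default: float | None = None) -> KinetomeTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    return KinetomeTable(
        kcat=dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float))),
        default=default,
    )


def read_medium_tsv(path) -> MediumTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    return MediumTable(
        uptake=dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))
    )
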