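"""Read, validate and write constraint-based metabolic models.

Two on-disk dialects are supported and both are approximations of the many
genome-scale model exports in circulation (the source dialect of any given
study is rarely recorded):

* ``cobra-json`` — the cobrapy JSON schema (``metabolites`` / ``reactions`` /
  ``genes`` arrays, stoichiometry as a ``metabolites`` mapping per reaction).
* ``tabular`` — a directory of three TSVs (``metabolites.tsv``,
  ``reactions.tsv`` with ``"A[c]:-1;B[c]:1"``-style stoichiometry strings and
  infix GPR text, ``genes.tsv``), designed to be hand-editable in tests.

Metabolite ids may carry their compartment as a ``[x]`` suffix or a ``_x``
suffix; they are normalized to ``[x]`` internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _gpr
from .errors import ModelParseError, ModelValidationError

_JSON_INDENT = 1


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lb: float
    ub: float
    subsystem: str = ""
    gpr: str = ""

    def gpr_tree(self):
        return _gpr.parse(self.gpr)


@dataclass
class MetabolicModel:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    genes: list[str] = field(default_factory=list)

    # -- lookups ---------------------------------------------------------
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def get_reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    def stoichiometric_matrix(self):
        """Dense S (metabolites x reactions), with row/column id lists."""
        met_ids = self.metabolite_ids()
        rxn_ids = self.reaction_ids()
        met_index = {m: i for i, m in enumerate(met_ids)}
        S = np.zeros((len(met_ids), len(rxn_ids)))
        for j, rxn in enumerate(self.reactions):
            for met, coef in rxn.stoichiometry.items():
                S[met_index[met], j] = coef
        return S, met_ids, rxn_ids

    def default_bounds(self) -> dict[str, tuple[float, float]]:
        return {r.id: (r.lb, r.ub) for r in self.reactions}

    # -- validation ------------------------------------------------------
    def validate(self) -> "MetabolicModel":
        met_ids = self.metabolite_ids()
        seen: set[str] = set()
        for m in self.metabolites:
            if m.id in seen:
                raise ModelValidationError(f"duplicate metabolite id {m.id!r}")
            seen.add(m.id)
            if not m.compartment:
                raise ModelValidationError(f"metabolite {m.id!r} has empty compartment")
        met_set = set(met_ids)
        rxn_seen: set[str] = set()
        gene_set = set(self.genes)
        for r in self.reactions:
            if r.id in rxn_seen:
                raise ModelValidationError(f"duplicate reaction id {r.id!r}")
            rxn_seen.add(r.id)
            if not r.stoichiometry:
                raise ModelValidationError(f"reaction {r.id!r} has empty stoichiometry")
            if r.lb > r.ub:
                raise ModelValidationError(
                    f"reaction {r.id!r} has lb {r.lb} > ub {r.ub}"
                )
            for met in r.stoichiometry:
                if met not in met_set:
                    raise ModelValidationError(
                        f"reaction {r.id!r} references unknown metabolite {met!r}"
                    )
            for gene in _gpr.genes(r.gpr_tree()):
                if gene not in gene_set:
                    raise ModelValidationError(
                        f"reaction {r.id!r} GPR references unknown gene {gene!r}"
                    )
        return self


def normalize_met_id(met_id: str, compartment: str = "") -> str:
    """Normalize ``asp_L_c`` / ``asp_L[c]`` to the ``[c]``-suffixed form."""
    if met_id.endswith("]") and "[" in met_id:
        return met_id
    if compartment and met_id.endswith("_" + compartment):
        return met_id[: -len(compartment) - 1] + f"[{compartment}]"
    return met_id


def identify_exchanges(model: MetabolicModel) -> list[str]:
    """Boundary reactions: exactly one metabolite in the stoichiometry.

    Returned in model order, so the result is a set invariant under reaction
    reordering.
    """
    return [r.id for r in model.reactions if len(r.stoichiometry) == 1]


# ---------------------------------------------------------------------------
# cobra-json dialect
# ---------------------------------------------------------------------------


def _read_cobra_json(path: Path) -> MetabolicModel:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelParseError(f"{path}: not valid JSON ({exc})") from exc
    metabolites = []
    for rec in doc.get("metabolites", []):
        if "id" not in rec:
            raise ModelParseError(f"{path}: metabolite record without id: {rec!r}")
        comp = rec.get("compartment", "")
        metabolites.append(
            Metabolite(
                id=normalize_met_id(rec["id"], comp),
                name=rec.get("name", ""),
                compartment=comp,
            )
        )
    alias = {}
    for m in metabolites:
        alias[m.id] = m.id
        if m.id.endswith(f"[{m.compartment}]"):
            base = m.id[: -len(m.compartment) - 2]
            alias[f"{base}_{m.compartment}"] = m.id
    reactions = []
    for rec in doc.get("reactions", []):
        if "id" not in rec or "metabolites" not in rec:
            raise ModelParseError(f"{path}: malformed reaction record: {rec!r}")
        stoich = {}
        for met, coef in rec["metabolites"].items():
            stoich[alias.get(met, met)] = float(coef)
        reactions.append(
            Reaction(
                id=rec["id"],
                stoichiometry=stoich,
                lb=float(rec.get("lower_bound", -1000.0)),
                ub=float(rec.get("upper_bound", 1000.0)),
                subsystem=rec.get("subsystem", "") or "",
                gpr=rec.get("gene_reaction_rule", "") or "",
            )
        )
    genes = [g["id"] for g in doc.get("genes", [])]
    if not genes:
        inferred: set[str] = set()
        for r in reactions:
            inferred |= _gpr.genes(r.gpr_tree())
        genes = sorted(inferred)
    return MetabolicModel(metabolites, reactions, genes)


def _write_cobra_json(model: MetabolicModel, path: Path) -> None:
    doc = {
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.id,
                "metabolites": dict(r.stoichiometry),
                "lower_bound": r.lb,
                "upper_bound": r.ub,
                "gene_reaction_rule": r.gpr,
                "subsystem": r.subsystem,
            }
            for r in model.reactions
        ],
        "genes": [{"id": g, "name": g} for g in model.genes],
        "id": "fluxscreen_model",
        "compartments": {
            m.compartment: m.compartment for m in model.metabolites
        },
        "version": "1",
    }
    path.write_text(json.dumps(doc, indent=_JSON_INDENT, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# tabular dialect
# ---------------------------------------------------------------------------

_MET_COLS = ["id", "name", "compartment"]
_RXN_COLS = ["id", "stoichiometry", "lb", "ub", "subsystem", "gpr"]


def _parse_stoich_string(text: str, rxn_id: str) -> dict[str, float]:
    stoich: dict[str, float] = {}
    for part in text.split(";"):
        part = part.strip()
        if not part:
            continue
        if ":" not in part:
            raise ModelParseError(
                f"reaction {rxn_id!r}: bad stoichiometry term {part!r}"
            )
        met, _, coef = part.rpartition(":")
        try:
            stoich[met.strip()] = float(coef)
        except ValueError as exc:
            raise ModelParseError(
                f"reaction {rxn_id!r}: non-numeric coefficient in {part!r}"
            ) from exc
    return stoich


def _stoich_to_string(stoich: dict[str, float]) -> str:
    return ";".join(f"{met}:{coef:g}" for met, coef in stoich.items())


def _read_tsv_rows(path: Path, expected_cols: list[str]) -> list[dict[str, str]]:
    if not path.exists():
        raise ModelParseError(f"missing tabular model file {path}")
    lines = [
        ln for ln in path.read_text().splitlines() if ln and not ln.startswith("#")
    ]
    if not lines:
        raise ModelParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    missing = [c for c in expected_cols if c not in header]
    if missing:
        raise ModelParseError(f"{path}: missing columns {missing}")
    rows = []
    for ln in lines[1:]:
        cells = ln.split("\t")
        rows.append({col: cells[i] if i < len(cells) else "" for i, col in enumerate(header)})
    return rows


def _read_tabular(path: Path) -> MetabolicModel:
    mets = [
        Metabolite(
            id=normalize_met_id(row["id"], row["compartment"]),
            name=row["name"],
            compartment=row["compartment"],
        )
        for row in _read_tsv_rows(path / "metabolites.tsv", _MET_COLS)
    ]
    rxns = []
    for row in _read_tsv_rows(path / "reactions.tsv", _RXN_COLS):
        try:
            lb, ub = float(row["lb"]), float(row["ub"])
        except ValueError as exc:
            raise ModelParseError(
                f"reaction {row['id']!r}: non-numeric bound"
            ) from exc
        rxns.append(
            Reaction(
                id=row["id"],
                stoichiometry=_parse_stoich_string(row["stoichiometry"], row["id"]),
                lb=lb,
                ub=ub,
                subsystem=row["subsystem"],
                gpr=row["gpr"],
            )
        )
    genes_path = path / "genes.tsv"
    if genes_path.exists():
        genes = [row["id"] for row in _read_tsv_rows(genes_path, ["id"])]
    else:
        inferred: set[str] = set()
        for r in rxns:
            inferred |= _gpr.genes(r.gpr_tree())
        genes = sorted(inferred)
    return MetabolicModel(mets, rxns, genes)


def _write_tabular(model: MetabolicModel, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    met_lines = ["\t".join(_MET_COLS)]
    met_lines += [f"{m.id}\t{m.name}\t{m.compartment}" for m in model.metabolites]
    (path / "metabolites.tsv").write_text("\n".join(met_lines) + "\n")
    rxn_lines = ["\t".join(_RXN_COLS)]
    rxn_lines += [
        "\t".join(
            [
                r.id,
                _stoich_to_string(r.stoichiometry),
                f"{r.lb:g}",
                f"{r.ub:g}",
                r.subsystem,
                r.gpr,
            ]
        )
        for r in model.reactions
    ]
    (path / "reactions.tsv").write_text("\n".join(rxn_lines) + "\n")
    (path / "genes.tsv").write_text("\n".join(["id"] + list(model.genes)) + "\n")


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

_FORMATS = ("cobra-json", "tabular")


def read_model(path, format: str = "cobra-json") -> MetabolicModel:
    """Read and validate a metabolic model.

    ``format="cobra-json"`` expects a single JSON file; ``format="tabular"``
    expects a directory with the three-TSV dialect.
    """
    if format not in _FORMATS:
        raise ValueError(f"unknown model format {format!r}; expected one of {_FORMATS}")
    path = Path(path)
    if format == "cobra-json":
        model = _read_cobra_json(path)
    else:
        model = _read_tabular(path)
    return model.validate()


def write_model(model: MetabolicModel, path, format: str = "cobra-json") -> None:
    if format not in _FORMATS:
        raise ValueError(f"unknown model format {format!r}; expected one of {_FORMATS}")
    path = Path(path)
    if format == "cobra-json":
        _write_cobra_json(model, path)
    else:
        _write_tabular(model, path)
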