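"""Ground-truth synthetic data: toy networks, expression and metabolomics.

The toy network is a miniature of a compartmentalized genome-scale model:
``n_pathways`` linear pathways, each its own subsystem with a dedicated
substrate exchange and product exchange, all feeding a shared core hub via a
side branch. One pathway ("AspLike") is the planted target: its enzymes are
down-regulated in case samples by a known multiplicative effect, and its
upstream intracellular substrate is recorded as the rescue metabolite the
knockout screen should recover as an agonist.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .gpmm_bounds import ExpressionMatrix, KinetomeTable, MediumTable
from .model_io import MetabolicModel, Metabolite, Reaction, write_model

ASP_LIKE = "AspLike"
DEFAULT_UPTAKE = -10.0


@dataclass
class GroundTruth:
    planted_subsystem: str
    enzyme_effect: float
    rescue_metabolites: list[str]
    planted_dm_metabolites: dict[str, float] = field(default_factory=dict)
    noise_sigma: float = 0.1
    seed: int = 0
    planted_genes: list[str] = field(default_factory=list)
    n_exchanges: int = 0

    def __post_init__(self):
        if not self.enzyme_effect > 0:
            raise ParameterError(f"enzyme_effect must be > 0, got {self.enzyme_effect}")


def make_toy_network(
    n_pathways: int,
    reactions_per_pathway: int,
    seed: int,
    enzyme_effect: float = 0.25,
    noise_sigma: float = 0.1,
) -> tuple[MetabolicModel, GroundTruth]:
    """Build a stoichiometrically consistent multi-subsystem toy model.

    Pathway p (subsystem ``pathway_p``, or ``AspLike`` for p = 0):

    * ``EX_sub_p``: sub_p[e] exchange (uptake) and ``EX_prod_p``: prod_p[e]
      exchange (secretion), subsystem "Exchange", no GPR;
    * ``T_p``: sub_p[e] -> sub_p[c], subsystem "Transport", no GPR;
    * a chain of ``reactions_per_pathway - 1`` enzyme-bearing reactions
      sub_p[c] -> i1 -> ... -> prod_p[e], one gene each;
    * one enzyme-bearing side reaction i1 -> core[c] feeding the shared hub.

    The hub drains through ``CoreSink``: core[c] -> waste[e] and ``EX_waste``.
    Every internal metabolite is both produced and consumed.
    """
    if n_pathways < 2:
        raise ParameterError(f"n_pathways must be >= 2, got {n_pathways}")
    if reactions_per_pathway < 3:
        raise ParameterError(
            f"reactions_per_pathway must be >= 3, got {reactions_per_pathway}"
        )
    rng = np.random.default_rng(seed)
    mets: list[Metabolite] = []
    rxns: list[Reaction] = []
    genes: list[str] = []

    def met(mid: str, comp: str) -> str:
        mets.append(Metabolite(id=mid, name=mid, compartment=comp))
        return mid

    core = met("core[c]", "c")
    waste = met("waste[e]", "e")
    chain_len = reactions_per_pathway - 1
    rescue: list[str] = []
    planted_genes: list[str] = []
    n_exchanges = 0
    for p in range(n_pathways):
        subsystem = ASP_LIKE if p == 0 else f"pathway_{p}"
        sub_e = met(f"sub{p}[e]", "e")
        sub_c = met(f"sub{p}[c]", "c")
        prod_e = met(f"prod{p}[e]", "e")
        inter = [met(f"i{p}_{k}[c]", "c") for k in range(1, chain_len)]
        nodes = [sub_c] + inter + [prod_e]
        rxns.append(
            Reaction(
                id=f"EX_sub{p}",
                stoichiometry={sub_e: -1.0},
                lb=-1000.0,
                ub=1000.0,
                subsystem="Exchange",
            )
        )
        rxns.append(
            Reaction(
                id=f"EX_prod{p}",
                stoichiometry={prod_e: -1.0},
                lb=0.0,
                ub=1000.0,
                subsystem="Exchange",
            )
        )
        n_exchanges += 2
        rxns.append(
            Reaction(
                id=f"T_{p}",
                stoichiometry={sub_e: -1.0, sub_c: 1.0},
                lb=0.0,
                ub=1000.0,
                subsystem="Transport",
            )
        )
        for k in range(chain_len):
            gene = f"g{p}_{k}"
            genes.append(gene)
            rxns.append(
                Reaction(
                    id=f"R{p}_{k}",
                    stoichiometry={nodes[k]: -1.0, nodes[k + 1]: 1.0},
                    lb=0.0,
                    ub=1000.0,
                    subsystem=subsystem,
                    gpr=gene,
                )
            )
            if p == 0:
                planted_genes.append(gene)
        side_gene = f"g{p}_side"
        genes.append(side_gene)
        rxns.append(
            Reaction(
                id=f"S_{p}",
                stoichiometry={inter[0] if inter else sub_c: -1.0, core: 1.0},
                lb=0.0,
                ub=1000.0,
                subsystem=subsystem,
                gpr=side_gene,
            )
        )
        if p == 0:
            planted_genes.append(side_gene)
            rescue = [sub_c] + inter + [sub_e]
    # composite GPRs on non-planted pathways to exercise OR/AND semantics
    rxns_by_id = {r.id: r for r in rxns}
    iso = "g1_0_iso"
    genes.append(iso)
    rxns_by_id["R1_0"].gpr = f"g1_0 or {iso}"
    if n_pathways > 2:
        sub2 = "g2_0_sub"
        genes.append(sub2)
        rxns_by_id["R2_0"].gpr = f"g2_0 and {sub2}"
    rxns.append(
        Reaction(
            id="CoreSink",
            stoichiometry={core: -1.0, waste: 1.0},
            lb=0.0,
            ub=1000.0,
            subsystem="Transport",
        )
    )
    rxns.append(
        Reaction(
            id="EX_waste",
            stoichiometry={waste: -1.0},
            lb=0.0,
            ub=1000.0,
            subsystem="Exchange",
        )
    )
    n_exchanges += 1
    model = MetabolicModel(metabolites=mets, reactions=rxns, genes=genes).validate()
    truth = GroundTruth(
        planted_subsystem=ASP_LIKE,
        enzyme_effect=enzyme_effect,
        rescue_metabolites=rescue,
        noise_sigma=noise_sigma,
        seed=seed,
        planted_genes=planted_genes,
        n_exchanges=n_exchanges,
    )
    # rng reserved for future topology randomization; draw once so that the
    # seed is part of the generator contract
    rng.random()
    return model, truth


def default_kinetome(model: MetabolicModel, kcat: float = 1.0) -> KinetomeTable:
    """kcat for every enzyme-bearing (GPR-carrying) reaction."""
    return KinetomeTable(kcat={r.id: kcat for r in model.reactions if r.gpr})


def default_medium(model: MetabolicModel, uptake: float = DEFAULT_UPTAKE) -> MediumTable:
    """Open every substrate exchange at the default uptake bound."""
    return MediumTable(
        uptake={
            r.id: uptake
            for r in model.reactions
            if r.id.startswith("EX_sub")
        }
    )


def simulate_expression(
    model: MetabolicModel,
    truth: GroundTruth,
    n_case: int,
    n_ctrl: int,
    seed: int,
) -> ExpressionMatrix:
    """Log-normal expression with the planted subsystem knocked down in cases.

    Each gene gets a baseline log-mean; samples are drawn log-normally around
    it with sd ``truth.noise_sigma``; planted genes are multiplied by
    ``truth.enzyme_effect`` in case samples only.
    """
    if n_case < 3 or n_ctrl < 3:
        raise ParameterError("need at least 3 samples per group")
    rng = np.random.default_rng(seed)
    genes = list(model.genes)
    base = rng.normal(np.log(5.0), 0.3, size=len(genes))
    n = n_case + n_ctrl
    samples = [f"case_{i}" for i in range(n_case)] + [
        f"ctrl_{i}" for i in range(n_ctrl)
    ]
    values = np.exp(base[:, None] + rng.normal(0.0, truth.noise_sigma, size=(len(genes), n)))
    planted = np.isin(genes, truth.planted_genes)
    values[np.ix_(planted, np.arange(n_case))] *= truth.enzyme_effect
    labels = {s: ("case" if s.startswith("case") else "control") for s in samples}
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples), labels=labels
    )


def simulate_metabolomics(
    n_patients: int,
    n_controls: int,
    n_metabolites: int,
    truth: GroundTruth,
    seed: int,
    tissue: str = "muscle",
    subject_sigma: float = 0.5,
    noise_sigma: float | None = None,
) -> pd.DataFrame:
    """Paired baseline/PEM abundances with a planted group-by-time interaction.

    Planted deltas (``truth.planted_dm_metabolites``, log2 scale) are added to
    the PEM timepoint of patients only. Subject offsets shift both timepoints
    equally and therefore cancel in the paired contrast.
    """
    if n_patients < 3 or n_controls < 3:
        raise ParameterError("need at least 3 subjects per group")
    rng = np.random.default_rng(seed)
    sigma = truth.noise_sigma if noise_sigma is None else noise_sigma
    metabolites = [f"m{i}" for i in range(n_metabolites)]
    for m in truth.planted_dm_metabolites:
        if m not in metabolites:
            raise ParameterError(f"planted DM metabolite {m!r} outside the table")
    subjects = [("patient", f"P{i}") for i in range(n_patients)] + [
        ("control", f"C{i}") for i in range(n_controls)
    ]
    base = rng.normal(10.0, 1.0, size=n_metabolites)  # log2 scale
    rows = []
    for group, subject in subjects:
        offset = rng.normal(0.0, subject_sigma)
        for timepoint in ("baseline", "PEM"):
            noise = rng.normal(0.0, sigma, size=n_metabolites)
            log2val = base + offset + noise
            if group == "patient" and timepoint == "PEM":
                for m, delta in truth.planted_dm_metabolites.items():
                    log2val[metabolites.index(m)] += delta
            for m, v in zip(metabolites, log2val):
                rows.append(
                    {
                        "metabolite": m,
                        "subject": subject,
                        "group": group,
                        "timepoint": timepoint,
                        "tissue": tissue,
                        "abundance": float(2.0 ** v),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# study directory emission
# ---------------------------------------------------------------------------


def write_study(
    outdir,
    n_pathways: int = 8,
    reactions_per_pathway: int = 4,
    n_case: int = 10,
    n_ctrl: int = 10,
    n_metabolites: int = 100,
    seed: int = 0,
    enzyme_effect: float = 0.25,
    noise_sigma: float = 0.1,
    planted_dm: dict[str, float] | None = None,
) -> Path:
    """Emit a self-contained study directory in the pipeline's own dialects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model, truth = make_toy_network(
        n_pathways,
        reactions_per_pathway,
        seed=seed,
        enzyme_effect=enzyme_effect,
        noise_sigma=noise_sigma,
    )
    if planted_dm is None:
        planted_dm = {f"m{i}": -0.8 for i in range(5)}
    truth.planted_dm_metabolites = dict(planted_dm)
    write_model(model, outdir / "model.json", format="cobra-json")
    write_model(model, outdir / "model_tabular", format="tabular")
    expr = simulate_expression(model, truth, n_case, n_ctrl, seed=seed + 1)
    expr.values.to_csv(outdir / "expression.tsv", sep="\t", float_format="%.10g")
    labels = pd.DataFrame(
        {"sample": expr.samples, "label": [expr.labels[s] for s in expr.samples]}
    )
    labels.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    kin = default_kinetome(model)
    pd.DataFrame(
        {"reaction_id": list(kin.kcat), "kcat_per_s": list(kin.kcat.values())}
    ).to_csv(outdir / "kinetome.tsv", sep="\t", index=False)
    med = default_medium(model)
    pd.DataFrame(
        {"exchange_id": list(med.uptake), "uptake_lb": list(med.uptake.values())}
    ).to_csv(outdir / "medium.tsv", sep="\t", index=False)
    metab = simulate_metabolomics(
        n_case, n_ctrl, n_metabolites, truth, seed=seed + 2
    )
    metab.to_csv(outdir / "metabolomics.tsv", sep="\t", index=False, float_format="%.10g")
    (outdir / "truth.json").write_text(
        json.dumps(dataclasses.asdict(truth), indent=1, sort_keys=True) + "\n"
    )
    return outdir
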