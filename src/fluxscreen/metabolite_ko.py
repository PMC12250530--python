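"""Metabolite effective scores (MES) from the knockout matrix.

MES_i = sum_j M[i,j] * sign(log2fc_j) * L_j, where L_j is the 0/1
significance indicator of reaction j's differential flux (optionally
|log2fc_j|). A metabolite whose knockout pushes significantly changed fluxes
further in the patient direction scores positive (agonist: supplementing it
is predicted to rescue the changes); the opposite scores negative
(antagonist). Significance comes from a normal background fit to the full MES
vector.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, ParameterError
from .pathway_da import adjust_fdr

L_WEIGHTS = ("indicator", "abs_log2fc")


def mes_scores(
    M: pd.DataFrame, diff: pd.DataFrame, l_weight: str = "indicator"
) -> pd.Series:
    """Per-metabolite MES from the knockout effect matrix and diff-flux table."""
    if l_weight not in L_WEIGHTS:
        raise ParameterError(f"l_weight must be one of {L_WEIGHTS}, got {l_weight!r}")
    if set(M.columns) != set(diff.index):
        extra = sorted(set(M.columns) ^ set(diff.index))
        raise AlignmentError(
            f"knockout matrix columns and diff-flux reactions differ: {extra[:10]}"
        )
    d = diff.reindex(M.columns)
    sign = d["sign"].to_numpy(dtype=float)
    if l_weight == "indicator":
        L = d["significant"].to_numpy(dtype=float)
    else:
        L = np.where(d["significant"], np.abs(d["log2fc"].to_numpy()), 0.0)
    mes = M.to_numpy(dtype=float) @ (sign * L)
    return pd.Series(mes, index=M.index, name="mes")


def mes_pvalues(mes: pd.Series, robust: bool = False) -> pd.DataFrame:
    """Normal-background two-sided p (and BH fdr) for each MES.

    The background (mu, sigma) is the sample mean/sd of the full MES vector;
    ``robust=True`` uses median and scaled MAD instead. sigma = 0 yields p = 1
    everywhere (no discrimination).
    """
    if len(mes) < 10:
        raise ParameterError(f"need >= 10 metabolites for a background fit, got {len(mes)}")
    x = mes.to_numpy(dtype=float)
    if robust:
        mu = float(np.median(x))
        sigma = float(stats.median_abs_deviation(x, scale="normal"))
    else:
        mu = float(x.mean())
        sigma = float(x.std(ddof=1))
    if sigma == 0:
        p = np.ones_like(x)
    else:
        p = 2.0 * stats.norm.sf(np.abs(x - mu) / sigma)
    out = pd.DataFrame({"mes": x, "p": p}, index=mes.index)
    out["fdr"] = adjust_fdr(p)
    return out


def classify(table: pd.DataFrame, fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Set class: agonist (mes > 0, fdr < threshold), antagonist (mes < 0), else neutral."""
    out = table.copy()
    cls = np.where(
        (out["mes"] > 0) & (out["fdr"] < fdr_threshold),
        "agonist",
        np.where((out["mes"] < 0) & (out["fdr"] < fdr_threshold), "antagonist", "neutral"),
    )
    out["class"] = cls
    return out


def mes_table(
    M: pd.DataFrame,
    diff: pd.DataFrame,
    l_weight: str = "indicator",
    robust: bool = False,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Full MESTable: scores, normal-background p/fdr, agonist/antagonist class."""
    mes = mes_scores(M, diff, l_weight=l_weight)
    table = mes_pvalues(mes, robust=robust)
    return classify(table, fdr_threshold=fdr_threshold).sort_values(
        "mes", ascending=False
    )


def base_name(met_id: str) -> str:
    """Strip the compartment qualifier: ``asp_L[c]`` -> ``asp_L``."""
    if met_id.endswith("]") and "[" in met_id:
        return met_id[: met_id.rindex("[")]
    return met_id


def aggregate_by_base(mes: pd.Series) -> pd.Series:
    """Sum MES across compartments of the same base metabolite."""
    grouped = mes.groupby([base_name(m) for m in mes.index]).sum()
    grouped.name = "mes"
    return grouped
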