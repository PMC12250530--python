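"""Paired pre/post metabolomics contrast between patient and control groups.

Each subject's response is the paired log2 change (post minus baseline) per
metabolite; the differential metabolite (DM) statistic is the difference of
the group means of those changes, tested with the same empirical-Bayes
moderated two-sample machinery used for fluxes. The paired design removes
subject-specific offsets by construction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .diff_flux import moderated_t_test
from .errors import ModelValidationError, ParameterError
from .pathway_da import adjust_fdr

logger = logging.getLogger(__name__)

GROUPS = ("patient", "control")
TIMEPOINTS = ("baseline", "PEM")

_COLUMNS = ["metabolite", "subject", "group", "timepoint", "abundance"]


def validate_abundance_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format table: required columns, positive values, unique cells."""
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ModelValidationError(f"abundance table missing columns {missing}")
    bad = df[df["abundance"] <= 0]
    if len(bad):
        row = bad.iloc[0]
        raise ModelValidationError(
            "non-positive abundance for metabolite "
            f"{row['metabolite']!r}, subject {row['subject']!r}, "
            f"timepoint {row['timepoint']!r}"
        )
    dup = df.duplicated(subset=["metabolite", "subject", "timepoint"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ModelValidationError(
            f"duplicate observation for metabolite {row['metabolite']!r}, "
            f"subject {row['subject']!r}, timepoint {row['timepoint']!r}"
        )
    unknown = set(df["timepoint"]) - set(TIMEPOINTS)
    if unknown:
        raise ModelValidationError(f"unknown timepoints {unknown}")
    return df


def paired_log2_change(df: pd.DataFrame):
    """Per-subject paired deltas: log2(post) - log2(baseline) per metabolite.

    Returns ``(deltas, groups)`` where ``deltas`` is metabolites x subjects
    and ``groups`` maps each retained subject to its group. Subjects missing
    a timepoint for a metabolite are dropped for that metabolite
    (complete-pairs analysis); whole-subject drops are logged.
    """
    validate_abundance_table(df)
    wide = df.pivot_table(
        index="metabolite",
        columns=["subject", "timepoint"],
        values="abundance",
        aggfunc="first",
    )
    subjects = sorted({s for s, _ in wide.columns})
    groups = (
        df.drop_duplicates("subject").set_index("subject")["group"].to_dict()
    )
    deltas = {}
    dropped = []
    for s in subjects:
        cols = wide[s] if s in wide.columns.get_level_values(0) else None
        if cols is None or "baseline" not in cols or "PEM" not in cols:
            dropped.append(s)
            continue
        delta = np.log2(cols["PEM"]) - np.log2(cols["baseline"])
        if delta.notna().sum() == 0:
            dropped.append(s)
            continue
        deltas[s] = delta
    if dropped:
        logger.info("dropped %d subject(s) missing a timepoint: %s", len(dropped), dropped)
    out = pd.DataFrame(deltas)
    return out, {s: groups[s] for s in out.columns}


def dm_statistic(deltas: pd.DataFrame, groups) -> pd.DataFrame:
    """DMTable: dm = mean patient delta - mean control delta, moderated p, BH fdr."""
    patients = [s for s in deltas.columns if groups.get(s) == "patient"]
    controls = [s for s in deltas.columns if groups.get(s) == "control"]
    if len(patients) < 2 or len(controls) < 2:
        raise ParameterError(
            f"need >= 2 subjects per group, got {len(patients)} patient(s) "
            f"and {len(controls)} control(s)"
        )
    labels = {s: "case" for s in patients} | {s: "control" for s in controls}
    tt = moderated_t_test(deltas, labels)
    out = pd.DataFrame(
        {
            "dm": deltas[patients].mean(axis=1) - deltas[controls].mean(axis=1),
            "t_mod": tt["t_mod"],
            "p": tt["p"],
        },
        index=deltas.index,
    )
    out["fdr"] = adjust_fdr(out["p"].to_numpy())
    out.attrs.update(tt.attrs)
    return out


def read_metabolomics_tsv(path) -> pd.DataFrame:
    """Long-format TSV: metabolite, subject, group, timepoint, tissue, abundance."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df["abundance"] = df["abundance"].astype(float)
    return df


def dm_per_tissue(df: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Run the paired contrast separately for each tissue in the table."""
    out = {}
    tissues = df["tissue"].unique() if "tissue" in df.columns else [""]
    for tissue in tissues:
        sub = df[df["tissue"] == tissue] if "tissue" in df.columns else df
        deltas, groups = paired_log2_change(sub)
        out[str(tissue)] = dm_statistic(deltas, groups)
    return out
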