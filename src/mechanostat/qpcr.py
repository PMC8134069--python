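"""Relative qPCR quantitation by the 2^-ddCt (Livak) method.

Cycle-threshold (Ct) values of each target gene are normalized to an
endogenous reference gene (RpL32 by default) within each sample
(dCt = Ct_target - Ct_reference), then to the control condition
(ddCt = mean dCt_treated - mean dCt_control; for paired designs the mean of
within-pair differences).  Relative quantity rq = 2^-ddCt assumes perfect
amplification efficiency (doubling per cycle); an efficiency parameter is
exposed for completeness.  p-values come from two-sided t-tests on the
reference-normalized dCt values (paired t for paired designs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "REFERENCE_GENE",
    "CT_COLUMNS",
    "ExpressionResult",
    "validate_ct_table",
    "average_technical_replicates",
    "delta_delta_ct",
    "expression_timecourse",
]

REFERENCE_GENE = "RpL32"
CT_COLUMNS = ["sample_id", "condition", "gene", "replicate_id", "replicate_kind", "ct"]
CONDITIONS = ("control", "treated")
CT_RANGE = (5.0, 40.0)


@dataclass
class ExpressionResult:
    gene: str
    delta_delta_ct: float
    rq: float
    rq_sd: float
    percent_change: float
    p_value: float
    n_treated: int
    n_control: int
    design: str
    flags: tuple = ()


def validate_ct_table(table: pd.DataFrame, reference: str = REFERENCE_GENE) -> pd.DataFrame:
    """Validate a long-format Ct table; flags (not drops) implausible Cts."""
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    table = table.copy()
    bad = set(table["condition"].unique()) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown condition label(s): {sorted(bad)}")
    table["ct"] = pd.to_numeric(table["ct"])
    table["ct_flagged"] = (table["ct"] < CT_RANGE[0]) | (table["ct"] > CT_RANGE[1])
    for sample, sub in table.groupby("sample_id"):
        if reference not in set(sub["gene"]):
            raise ValueError(f"missing reference gene: {reference!r} absent for sample {sample!r}")
    return table


def average_technical_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse technical replicates to one Ct per sample x gene.

    Arithmetic mean of technical-replicate Cts; their SD is kept as
    ``ct_sd`` (NaN when only one replicate, flagged in ``single_replicate``).
    Biological replicates (distinct samples) are left untouched.
    """
    tech = table[table["replicate_kind"] == "technical"]
    other = table[table["replicate_kind"] != "technical"]
    group_cols = [c for c in ("sample_id", "condition", "timepoint", "gene")
                  if c in table.columns]
    parts = []
    if len(tech):
        agg = (tech.groupby(group_cols, as_index=False)
               .agg(ct=("ct", "mean"), ct_sd=("ct", "std"), n_technical=("ct", "size")))
        agg["single_replicate"] = agg["n_technical"] == 1
        parts.append(agg)
    if len(other):
        o = other[group_cols + ["ct"]].copy()
        o["ct_sd"] = np.nan
        o["n_technical"] = 1
        o["single_replicate"] = True
        parts.append(o)
    return pd.concat(parts, ignore_index=True)


def _delta_ct(avg: pd.DataFrame, target: str, reference: str) -> pd.DataFrame:
    """Per-sample dCt = Ct_target - Ct_reference, one row per sample x condition.

    A sample_id may legitimately appear in both conditions (paired designs,
    e.g. contralateral organs of one animal).
    """
    rows = []
    for (sample, cond), sub in avg.groupby(["sample_id", "condition"]):
        t = sub[sub["gene"] == target]
        r = sub[sub["gene"] == reference]
        if len(t) != 1 or len(r) != 1:
            continue
        t, r = t.iloc[0], r.iloc[0]
        var = (0.0 if pd.isna(t["ct_sd"]) else t["ct_sd"] ** 2 / t["n_technical"]) \
            + (0.0 if pd.isna(r["ct_sd"]) else r["ct_sd"] ** 2 / r["n_technical"])
        rows.append({"sample_id": sample, "condition": cond,
                     "dct": t["ct"] - r["ct"], "var_dct": var})
    if not rows:
        raise ValueError("missing reference gene: no sample has both target and reference")
    return pd.DataFrame(rows).set_index("sample_id")


def delta_delta_ct(table: pd.DataFrame, target: str,
                   reference: str = REFERENCE_GENE, design: str = "unpaired",
                   efficiency: float = 2.0, test: str = "student") -> ExpressionResult:
    """2^-ddCt relative quantitation of ``target`` vs the control condition.

    ``design='paired'`` pairs treated/control by sample_id (e.g. contralateral
    organs of the same animal) and uses the paired t-test; ``'unpaired'``
    compares condition means with a two-sample t-test on dCt values.
    rq_sd is the delta-method propagation of technical-replicate SDs through
    ddCt: sd(rq) = ln(eff) * rq * sd(ddCt).
    """
    table = validate_ct_table(table, reference)
    avg = average_technical_replicates(table)
    d = _delta_ct(avg, target, reference)
    treated = d[d["condition"] == "treated"]
    control = d[d["condition"] == "control"]
    flags = []

    if design == "paired":
        pairs = treated.index.intersection(control.index)
        if len(pairs) < 2:
            raise ValueError("insufficient replication: need >= 2 pairs")
        diffs = treated.loc[pairs, "dct"] - control.loc[pairs, "dct"]
        ddct = float(diffs.mean())
        var_ddct = float((treated.loc[pairs, "var_dct"]
                          + control.loc[pairs, "var_dct"]).sum()) / len(pairs) ** 2
        if diffs.std(ddof=1) < 1e-12:
            p = 1.0 if ddct == 0 else 0.0
        else:
            p = float(stats.ttest_rel(treated.loc[pairs, "dct"],
                                      control.loc[pairs, "dct"]).pvalue)
        n_t = n_c = len(pairs)
    elif design == "unpaired":
        if len(treated) < 2 or len(control) < 2:
            raise ValueError("insufficient replication: need >= 2 samples per condition")
        ddct = float(treated["dct"].mean() - control["dct"].mean())
        var_ddct = (float(treated["var_dct"].sum()) / len(treated) ** 2
                    + float(control["var_dct"].sum()) / len(control) ** 2)
        if treated["dct"].std(ddof=1) < 1e-12 and control["dct"].std(ddof=1) < 1e-12:
            p = 1.0 if ddct == 0 else 0.0
        else:
            p = float(stats.ttest_ind(treated["dct"], control["dct"],
                                      equal_var=(test == "student")).pvalue)
        n_t, n_c = len(treated), len(control)
    else:
        raise ValueError("design must be 'paired' or 'unpaired'")

    rq = float(efficiency ** (-ddct))
    rq_sd = float(np.log(efficiency) * rq * np.sqrt(var_ddct))
    if avg.loc[avg["gene"].isin([target, reference]), "single_replicate"].any():
        flags.append("single technical replicate")
    return ExpressionResult(
        gene=target, delta_delta_ct=ddct, rq=rq, rq_sd=rq_sd,
        percent_change=100.0 * (rq - 1.0), p_value=p,
        n_treated=n_t, n_control=n_c, design=design, flags=tuple(flags))


def expression_timecourse(tables: dict, targets: list[str],
                          reference: str = REFERENCE_GENE,
                          design: str = "unpaired", **kwargs) -> pd.DataFrame:
    """Per-timepoint relative quantitation, each against its own control cohort.

    ``tables`` maps timepoint label -> Ct table containing both conditions.
    Returns a DataFrame with one row per gene x timepoint.
    """
    rows = []
    for tp, table in tables.items():
        conditions = set(table["condition"].unique())
        if "control" not in conditions:
            raise ValueError(f"missing control cohort at timepoint {tp!r}")
        for gene in targets:
            res = delta_delta_ct(table, gene, reference=reference,
                                 design=design, **kwargs)
            rows.append({"timepoint": tp, "gene": gene,
                         "delta_delta_ct": res.delta_delta_ct, "rq": res.rq,
                         "rq_sd": res.rq_sd, "percent_change": res.percent_change,
                         "p_value": res.p_value})
    return pd.DataFrame(rows)
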