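"""ChIP-qPCR relative enrichment.

Two normalization schemes:

* double normalization — target DNA normalized first to an internal control
  amplicon (e.g. the transcriptionally inert HSF locus, At4g17740) and then
  to the corresponding amount in the input fraction;
* input-only normalization per condition followed by a between-condition
  ratio (used to express e.g. +DEX vs -DEX fold changes).

Quantities derive from cycle thresholds as Q = efficiency^(-Ct); with
efficiency 2 the double normalization is the classic 2^-ddCt.  Technical
replicates are aggregated as mean Ct per (amplicon, fraction, condition)
before any ratio; the SD of each ratio is propagated on the log scale by
the delta method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("amplicon", "fraction", "condition", "Ct")
FRACTIONS = ("IP", "input")


@dataclass
class EnrichmentTable:
    """Per (amplicon, condition) enrichment with a log2-scale SD."""

    table: pd.DataFrame  # columns: amplicon, condition, enrichment, log2_sd


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"qPCR table lacks required column {col!r}")
    if (table["Ct"] <= 0).any():
        raise ValueError("Ct values must be > 0")
    bad = set(table["fraction"]) - set(FRACTIONS)
    if bad:
        raise ValueError(f"unknown fraction label(s): {sorted(bad)}")
    if "efficiency" not in table.columns:
        table = table.assign(efficiency=2.0)
    eff = table["efficiency"]
    if ((eff <= 1) | (eff > 2)).any():
        raise ValueError("amplification efficiency must be in (1, 2]")
    return table


def _aggregate(table: pd.DataFrame) -> pd.DataFrame:
    """Mean Ct and its standard error per (amplicon, fraction, condition)."""
    grouped = table.groupby(["amplicon", "fraction", "condition"], sort=False)
    agg = grouped.agg(
        mean_ct=("Ct", "mean"),
        sd_ct=("Ct", lambda x: x.std(ddof=1) if len(x) > 1 else 0.0),
        n=("Ct", "size"),
        efficiency=("efficiency", "mean"),
    ).reset_index()
    agg["se_ct"] = agg["sd_ct"] / np.sqrt(agg["n"])
    return agg


def _lookup(agg: pd.DataFrame, amplicon: str, fraction: str, condition: str) -> pd.Series:
    rows = agg[
        (agg["amplicon"] == amplicon)
        & (agg["fraction"] == fraction)
        & (agg["condition"] == condition)
    ]
    if rows.empty:
        raise ValueError(
            f"missing qPCR rows for amplicon={amplicon!r}, fraction={fraction!r}, "
            f"condition={condition!r}"
        )
    return rows.iloc[0]


def relative_enrichment(
    table: pd.DataFrame, control_amplicon: str
) -> EnrichmentTable:
    """Double-normalized enrichment per (target amplicon, condition).

    enrichment = [Q_IP(target) / Q_IP(control)] / [Q_input(target) /
    Q_input(control)] with Q = efficiency^(-Ct), i.e. normalize to the
    internal control first, then to the input.  The control amplicon itself
    has enrichment exactly 1 by construction.
    """
    table = _validate(table)
    agg = _aggregate(table)
    conditions = agg["condition"].unique()
    amplicons = agg["amplicon"].unique()
    if control_amplicon not in set(amplicons):
        raise ValueError(f"control amplicon {control_amplicon!r} absent from table")
    rows = []
    for cond in conditions:
        ctrl_ip = _lookup(agg, control_amplicon, "IP", cond)
        ctrl_in = _lookup(agg, control_amplicon, "input", cond)
        for amp in amplicons:
            tgt_ip = _lookup(agg, amp, "IP", cond)
            tgt_in = _lookup(agg, amp, "input", cond)
            eff = tgt_ip["efficiency"]
            log_eff = math.log2(eff)
            # log2 enrichment = -ddCt scaled by log2(efficiency)
            ddct = (tgt_ip["mean_ct"] - ctrl_ip["mean_ct"]) - (
                tgt_in["mean_ct"] - ctrl_in["mean_ct"]
            )
            log2_enr = -ddct * log_eff
            var = sum(
                (log_eff * r["se_ct"]) ** 2 for r in (tgt_ip, ctrl_ip, tgt_in, ctrl_in)
            )
            rows.append((amp, cond, 2.0 ** log2_enr, math.sqrt(var)))
    return EnrichmentTable(
        pd.DataFrame(rows, columns=["amplicon", "condition", "enrichment", "log2_sd"])
    )


def input_normalized(table: pd.DataFrame) -> EnrichmentTable:
    """Input-only normalization: Q_IP / Q_input per (amplicon, condition)."""
    table = _validate(table)
    agg = _aggregate(table)
    rows = []
    for (amp, cond), _ in agg.groupby(["amplicon", "condition"], sort=False):
        ip = _lookup(agg, amp, "IP", cond)
        inp = _lookup(agg, amp, "input", cond)
        log_eff = math.log2(ip["efficiency"])
        log2_enr = -(ip["mean_ct"] - inp["mean_ct"]) * log_eff
        var = (log_eff * ip["se_ct"]) ** 2 + (log_eff * inp["se_ct"]) ** 2
        rows.append((amp, cond, 2.0 ** log2_enr, math.sqrt(var)))
    return EnrichmentTable(
        pd.DataFrame(rows, columns=["amplicon", "condition", "enrichment", "log2_sd"])
    )


def condition_ratio(
    enrichments: EnrichmentTable, cond_a: str, cond_b: str
) -> pd.DataFrame:
    """Per-amplicon fold change enrichment(cond A) / enrichment(cond B).

    SDs of the two enrichments combine in quadrature on the log2 scale.
    """
    t = enrichments.table
    for cond in (cond_a, cond_b):
        if cond not in set(t["condition"]):
            raise ValueError(f"condition {cond!r} absent from enrichment table")
    rows = []
    for amp in t["amplicon"].unique():
        ea = t[(t["amplicon"] == amp) & (t["condition"] == cond_a)]
        eb = t[(t["amplicon"] == amp) & (t["condition"] == cond_b)]
        if ea.empty or eb.empty:
            continue
        fold = float(ea["enrichment"].iloc[0] / eb["enrichment"].iloc[0])
        sd = math.sqrt(float(ea["log2_sd"].iloc[0]) ** 2 + float(eb["log2_sd"].iloc[0]) ** 2)
        rows.append((amp, fold, sd))
    return pd.DataFrame(rows, columns=["amplicon", "fold", "log2_sd"])
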