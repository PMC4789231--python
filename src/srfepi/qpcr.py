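"""Relative qPCR quantification and ChIP-qPCR binding calls.

Expression fold changes use the ddCT method against the Arbp reference gene
(stable across kainic-acid epilepsy phases): per-sample dCt = Ct_target -
Ct_reference, replicates averaged on the Ct scale, and
fold = 2^-(mean dCt_case - mean dCt_control).

ChIP signal is expressed as percent of input,
    percent = 100 * input_fraction * 2^(Ct_input - Ct_IP),
with the input dilution recorded per experiment rather than folded into a
constant.  An amplicon is called SRF-bound in a condition when its SRF
percent-of-input exceeds both controls more than 2-fold (strictly): the
Arbp-exon negative-control amplicon precipitated with SRF, and the IgG mock
precipitation of the same amplicon.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

REFERENCE_GENE = "Arbp"
NEGATIVE_CONTROL_AMPLICON = "Arbp exon"

CT_COLUMNS = ["sample_id", "condition", "target_gene", "ct_target", "ct_reference"]
CHIP_COLUMNS = ["antibody", "amplicon_id", "condition", "ct_ip", "ct_input", "input_fraction"]


def _check_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{what} table missing columns {sorted(missing)}")


def ddct_fold_change(
    table: pd.DataFrame, case_condition: str, control_condition: str
) -> pd.Series:
    """Per-gene linear fold change of case over control by ddCT."""
    _check_columns(table, CT_COLUMNS, "Ct")
    present = set(table["condition"])
    for cond in (case_condition, control_condition):
        if cond not in present:
            raise ValueError(f"condition {cond!r} absent from Ct table")
    if table[["ct_target", "ct_reference"]].isna().any().any():
        raise ValueError("missing Ct values (reference rows incomplete?)")
    dct = table.assign(dct=table["ct_target"] - table["ct_reference"])
    means = dct.groupby(["target_gene", "condition"])["dct"].mean().unstack("condition")
    for cond in (case_condition, control_condition):
        if means[cond].isna().any():
            genes = means.index[means[cond].isna()].tolist()
            raise ValueError(f"genes missing condition {cond!r}: {genes}")
    fold = 2.0 ** -(means[case_condition] - means[control_condition])
    fold.name = "fold_change"
    return fold


def percent_input(
    ct_ip: float | np.ndarray,
    ct_input: float | np.ndarray,
    input_fraction: float | np.ndarray,
) -> float | np.ndarray:
    """ChIP recovery as a percentage of the pre-IP chromatin."""
    frac = np.asarray(input_fraction, dtype=float)
    if (frac <= 0).any() if frac.ndim else frac <= 0:
        raise ValueError("input_fraction must be positive")
    out = 100.0 * frac * 2.0 ** (np.asarray(ct_input, float) - np.asarray(ct_ip, float))
    return float(out) if np.ndim(out) == 0 else out


def call_binding(
    table: pd.DataFrame,
    threshold: float = 2.0,
    negative_control: str = NEGATIVE_CONTROL_AMPLICON,
) -> pd.DataFrame:
    """Per-(amplicon, condition) percent-of-input table with binding calls.

    Replicate rows are averaged on the percent scale.  ``bound`` is True only
    when both enrichment ratios strictly exceed ``threshold``; rows with a
    zero denominator are flagged ``undefined_ratio`` and never bound.
    """
    _check_columns(table, CHIP_COLUMNS, "ChIP Ct")
    if negative_control not in set(table["amplicon_id"]):
        raise ValueError(f"negative-control amplicon {negative_control!r} absent")
    df = table.assign(
        percent=percent_input(
            table["ct_ip"].to_numpy(),
            table["ct_input"].to_numpy(),
            table["input_fraction"].to_numpy(),
        )
    )
    wide = (
        df.groupby(["amplicon_id", "condition", "antibody"])["percent"]
        .mean()
        .unstack("antibody")
    )
    if not {"SRF", "IgG"}.issubset(wide.columns):
        raise ValueError("ChIP table must contain SRF and IgG antibody rows")
    results = []
    for (amplicon, condition), row in wide.iterrows():
        arbp = wide["SRF"].get((negative_control, condition), np.nan)
        srf, igg = row["SRF"], row["IgG"]
        undefined = not np.isfinite(arbp) or arbp == 0 or not np.isfinite(igg) or igg == 0
        ratio_arbp = srf / arbp if not undefined else np.nan
        ratio_igg = srf / igg if not undefined else np.nan
        results.append(
            {
                "amplicon_id": amplicon,
                "condition": condition,
                "percent_input_srf": srf,
                "percent_input_igg": igg,
                "ratio_vs_arbp": ratio_arbp,
                "ratio_vs_igg": ratio_igg,
                "undefined_ratio": undefined,
                "bound": bool(
                    not undefined and ratio_arbp > threshold and ratio_igg > threshold
                ),
            }
        )
    out = pd.DataFrame(results)
    # the negative control is a control, not a call
    out.loc[out["amplicon_id"] == negative_control, "bound"] = False
    return out


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, CT_COLUMNS, "Ct")
    return df


def read_chip_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, CHIP_COLUMNS, "ChIP Ct")
    return df
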