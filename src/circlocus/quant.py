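"""Relative RT-qPCR quantification with a two-housekeeper reference.

Normalization: dCt = Ct_target - mean(Ct_hk1, Ct_hk2) per sample (the
arithmetic mean of Ct values, i.e. the geometric mean of linear
abundances), value = 2**(-dCt), rescaled so the mean of a chosen reference
condition is exactly 1. Amplification efficiency is fixed at 2 per cycle;
technical replicates are averaged on the Ct scale before dCt.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("sample", "target", "ct")


def _prep(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    keys = ["sample", "target"] + (["condition"] if "condition" in table.columns else [])
    # technical replicates averaged on the Ct scale first
    return table.groupby(keys, as_index=False)["ct"].mean()


def relative_expression(table: pd.DataFrame, target: str,
                        housekeepers: tuple[str, str] = ("HK1", "HK2"),
                        reference_condition: str | None = None) -> pd.DataFrame:
    """Per-sample normalized expression of ``target``.

    ``table`` columns: sample, target, ct, optionally condition. When a
    reference condition is given (a condition value, or a sample id if no
    condition column exists), values are rescaled so its mean is 1.
    """
    t = _prep(table)
    wide = t.pivot_table(index="sample", columns="target", values="ct")
    for hk in housekeepers:
        bad = wide.index[wide[hk].isna()] if hk in wide.columns else wide.index
        if len(bad):
            raise ValueError(f"housekeeper {hk!r} missing in sample(s): {list(bad)}")
    if target not in wide.columns:
        raise ValueError(f"target {target!r} not in table")
    hk_mean = (wide[housekeepers[0]] + wide[housekeepers[1]]) / 2.0
    dct = wide[target] - hk_mean
    values = np.power(2.0, -dct)
    out = pd.DataFrame({"sample": wide.index, "target": target,
                        "value": values.to_numpy()})
    if "condition" in t.columns:
        cond = t.drop_duplicates("sample").set_index("sample")["condition"]
        out["condition"] = out["sample"].map(cond)
    if reference_condition is not None:
        if "condition" in out.columns:
            ref = out.loc[out["condition"] == reference_condition, "value"]
        else:
            ref = out.loc[out["sample"] == reference_condition, "value"]
        if ref.empty:
            raise ValueError(f"reference condition {reference_condition!r} matches no sample")
        out["value"] = out["value"] / ref.mean()
    return out.reset_index(drop=True)


def circ_linear_ratio(table: pd.DataFrame, circ_target: str, linear_target: str,
                      housekeepers: tuple[str, str] = ("HK1", "HK2")) -> pd.DataFrame:
    """Per-sample circular/linear ratio and per-condition predominance flag.

    A condition is flagged ``circ_predominant`` when the mean ratio exceeds
    1 — the circle is then the gene's main transcriptional output. Samples
    with zero linear signal are flagged and their ratio omitted (NaN).
    """
    circ = relative_expression(table, circ_target, housekeepers)
    lin = relative_expression(table, linear_target, housekeepers)
    merged = circ.merge(lin, on=[c for c in ("sample", "condition") if c in circ.columns],
                        suffixes=("_circ", "_linear"))
    zero = merged["value_linear"] == 0
    merged["ratio"] = np.where(zero, np.nan, merged["value_circ"] / merged["value_linear"])
    merged["zero_linear"] = zero
    cols = ["sample", "ratio", "zero_linear"]
    if "condition" in merged.columns:
        merged["circ_predominant"] = merged.groupby("condition")["ratio"] \
            .transform("mean") > 1.0
        cols = ["sample", "condition", "ratio", "zero_linear", "circ_predominant"]
    else:
        merged["circ_predominant"] = merged["ratio"].mean() > 1.0
        cols.append("circ_predominant")
    return merged[cols]
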