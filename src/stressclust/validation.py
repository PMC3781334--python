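"""Small statistics behind the validation figures: ChIP-qPCR percent input,
one-way ANOVA, and specific-vs-IgG group comparisons.

Percent input uses the standard 2^deltaCt form: the input Ct is first
adjusted for the fraction of chromatin the input lane represents
(Ct_input - log2(1/fraction)), then percent = 100 * 2^(adjusted - Ct_ip).
Amplification efficiency is assumed to be 100%; no efficiency correction is
applied.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .calls import two_sample_t
from .errors import StressclustError


def percent_input(ct_ip, ct_input, input_fraction):
    """ChIP recovery as a percentage of total input chromatin.

    Accepts scalars or aligned arrays.  ``input_fraction`` is the fraction
    of chromatin loaded in the input lane (e.g. 0.01 for a 1% input).
    """
    ct_ip = np.asarray(ct_ip, dtype=float)
    ct_input = np.asarray(ct_input, dtype=float)
    frac = np.asarray(input_fraction, dtype=float)
    if (frac <= 0).any() or (frac > 1).any():
        raise StressclustError("input_fraction must be in (0, 1]")
    if (ct_ip <= 0).any() or (ct_input <= 0).any():
        raise StressclustError("Ct values must be positive")
    adjusted = ct_input - np.log2(1.0 / frac)
    out = 100.0 * np.exp2(adjusted - ct_ip)
    return float(out) if out.ndim == 0 else out


def one_way_anova(*groups) -> tuple[float, float]:
    """Classic between/within mean-square F-test over >=2 replicate groups.

    All-identical input follows the convention F = 0, p = 1.
    """
    if len(groups) < 2:
        raise StressclustError("ANOVA requires at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise StressclustError("each ANOVA group needs >=2 values")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    f, p = stats.f_oneway(*arrays)
    if math.isnan(f):  # zero within-group variance, unequal means
        return math.inf, 0.0
    return float(f), float(p)


def process_chip_table(df: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Percent input plus specific-vs-IgG t-tests per locus and condition.

    ``df`` needs columns (locus, antibody, condition, Ct_ip, Ct_input,
    input_fraction); antibody levels are 'specific' and 'IgG'.  Returns one
    row per (locus, condition) with group mean percent input for both
    antibodies and the two-tailed t-test p-value.
    """
    required = {"locus", "antibody", "condition", "Ct_ip", "Ct_input",
                "input_fraction"}
    missing = required - set(df.columns)
    if missing:
        raise StressclustError(f"ChIP table missing columns {sorted(missing)}")
    df = df.copy()
    df["percent_input"] = percent_input(df["Ct_ip"], df["Ct_input"],
                                        df["input_fraction"])
    rows = []
    for (locus, condition), sub in df.groupby(["locus", "condition"]):
        spec = sub.loc[sub["antibody"] == "specific", "percent_input"].to_numpy()
        igg = sub.loc[sub["antibody"] == "IgG", "percent_input"].to_numpy()
        t = p = np.nan
        if spec.size >= 2 and igg.size >= 2:
            t, p = two_sample_t(spec, igg)
        rows.append({"locus": locus, "condition": condition,
                     "mean_specific": spec.mean() if spec.size else np.nan,
                     "mean_IgG": igg.mean() if igg.size else np.nan,
                     "t": t, "p": p,
                     "significant": bool(p < alpha) if not np.isnan(p) else False})
    return pd.DataFrame(rows)
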