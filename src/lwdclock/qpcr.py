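"""Quantification formulas: comparative CT, reporter normalisation, ChIP.

``relative_expression`` implements the plain comparative CT method
(2^-dCT with dCT = CT_target - CT_reference, assuming doubling per
cycle, no efficiency correction).  ``normalize_to_timepoint`` rescales
a reporter series to its value at a reference time (e.g. LL14).
``chip_relative_enrichment`` converts IP/input CT pairs to
percent-of-input and ratios a target amplicon against a negative
control amplicon.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def relative_expression(ct_target, ct_reference) -> float:
    """2^-(ct_target - ct_reference) for scalar CT values."""
    if not (math.isfinite(ct_target) and math.isfinite(ct_reference)):
        raise ValueError("CT values must be finite")
    return 2.0 ** -(ct_target - ct_reference)


def mean_relative_expression(ct_targets, ct_references):
    """Mean of per-replicate 2^-dCT values, excluding undetermined CTs.

    Undetermined (NaN) CT pairs are dropped, not imputed; the count of
    excluded replicates is returned alongside.

    Returns
    -------
    (mean, sd, se, n_excluded)
    """
    ct_t = np.asarray(ct_targets, dtype=float)
    ct_r = np.asarray(ct_references, dtype=float)
    if ct_t.shape != ct_r.shape:
        raise ValueError("target and reference CT arrays must align")
    good = np.isfinite(ct_t) & np.isfinite(ct_r)
    n_excluded = int((~good).sum())
    vals = 2.0 ** -(ct_t[good] - ct_r[good])
    if vals.size == 0:
        return np.nan, np.nan, np.nan, n_excluded
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return float(vals.mean()), sd, sd / np.sqrt(vals.size), n_excluded


def expression_report(ct_table: pd.DataFrame, reference_gene: str) -> pd.DataFrame:
    """Tidy per-(sample, gene) 2^-dCT summary from a long CT table.

    ``ct_table`` needs columns sample, gene, replicate, ct.  Error bars
    are reported both as s.d. and s.e. over technical replicates.
    """
    required = {"sample", "gene", "replicate", "ct"}
    if not required.issubset(ct_table.columns):
        raise ValueError(f"ct_table must have columns {sorted(required)}")
    rows = []
    for sample, sub in ct_table.groupby("sample", sort=False):
        ref = sub[sub["gene"] == reference_gene].set_index("replicate")["ct"]
        for gene, g in sub[sub["gene"] != reference_gene].groupby("gene", sort=False):
            g = g.set_index("replicate")
            reps = g.index.intersection(ref.index)
            mean, sd, se, n_exc = mean_relative_expression(
                g.loc[reps, "ct"].to_numpy(), ref.loc[reps].to_numpy()
            )
            rows.append({
                "sample": sample, "gene": gene, "mean_rel_expr": mean,
                "sd": sd, "se": se, "n_replicates": len(reps) - n_exc,
                "n_excluded": n_exc,
            })
    return pd.DataFrame(rows)


def normalize_to_timepoint(t, y, t_ref: float):
    """Divide a series by its (linearly interpolated) value at ``t_ref``."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (t[0] <= t_ref <= t[-1]):
        raise ValueError("reference time outside the series range")
    ref = float(np.interp(t_ref, t, y))
    if ref <= 0:
        raise ValueError(
            f"value at reference time ({ref:g}) must be positive to normalise"
        )
    return y / ref


def percent_of_input(ct_ip: float, ct_input: float, input_fraction: float) -> float:
    """Percent-of-input from IP and input CTs with dilution adjustment."""
    if not 0 < input_fraction <= 1:
        raise ValueError("input_fraction must be in (0, 1]")
    ct_input_adj = ct_input - math.log2(1.0 / input_fraction)
    return 100.0 * 2.0 ** (ct_input_adj - ct_ip)


def chip_relative_enrichment(
    ct_ip_target: float,
    ct_input_target: float,
    ct_ip_control: float,
    ct_input_control: float,
    input_fraction: float,
) -> float:
    """Target-amplicon percent-of-input over control-amplicon percent-of-input."""
    return percent_of_input(ct_ip_target, ct_input_target, input_fraction) / \
        percent_of_input(ct_ip_control, ct_input_control, input_fraction)
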