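"""Efficiency-corrected relative qPCR expression (Pfaffl method).

ratio = E_target ** dCt_target / E_ref ** dCt_ref, with dCt defined as
Ct(control) - Ct(treated) and E the amplification fold per cycle (2.0 for
perfect doubling, giving the classic 2^-ddCt limit).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from rrbs_methkit import io as mkio


@dataclass(frozen=True)
class ExpressionMeasurement:
    target_gene: str
    reference_gene: str
    e_target: float
    e_ref: float
    dct_target: float  # Ct(control) - Ct(treated), target gene
    dct_ref: float     # Ct(control) - Ct(treated), reference gene

    def __post_init__(self) -> None:
        for label, e in (("E_target", self.e_target), ("E_ref", self.e_ref)):
            if not 1.0 < e <= 2.0:
                raise ValueError(f"{label}={e}: amplification efficiency must be in (1, 2]")
        for label, ct in (("dCt_target", self.dct_target), ("dCt_ref", self.dct_ref)):
            if not np.isfinite(ct):
                raise ValueError(f"{label} must be finite")


def pfaffl_ratio(meas: ExpressionMeasurement) -> float:
    """Relative expression of the target gene, efficiency corrected."""
    return meas.e_target ** meas.dct_target / meas.e_ref ** meas.dct_ref


def star_code(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def summarize_replicates(ratios: list[float] | np.ndarray) -> dict:
    """Mean +/- SD of replicate ratios and a two-sided one-sample t-test
    against 1.0 (no change). Fewer than 2 replicates: mean only, no test.
    A zero-variance set is degenerate: flagged, no test, no stars."""
    arr = np.asarray(ratios, dtype=float)
    if len(arr) == 0:
        raise ValueError("no replicate ratios")
    out = {"n": len(arr), "mean": float(arr.mean()),
           "sd": float(arr.std(ddof=1)) if len(arr) > 1 else float("nan"),
           "p_value": float("nan"), "stars": "", "degenerate": False}
    if len(arr) < 2:
        return out
    if arr.std(ddof=1) == 0:
        out["degenerate"] = True
        return out
    res = stats.ttest_1samp(arr, 1.0)
    out["p_value"] = float(res.pvalue)
    out["stars"] = star_code(out["p_value"])
    return out


def run_expression_table(ct_path: str | Path) -> pd.DataFrame:
    """Process a Ct TSV into Pfaffl ratios with replicate summaries.

    Expected columns: target_gene, reference_gene, replicate, e_target,
    e_ref, dct_target, dct_ref (efficiencies default to 2.0 when the
    column is absent or empty).
    """
    table = mkio.read_tsv(ct_path)
    required = {"target_gene", "reference_gene", "replicate", "dct_target", "dct_ref"}
    missing = required - set(table.columns)
    if missing:
        raise mkio.FormatError(f"{ct_path}: missing columns {sorted(missing)}")
    for col in ("e_target", "e_ref"):
        if col not in table.columns:
            table[col] = 2.0
        table[col] = table[col].fillna(2.0)
    rows = []
    for gene, sub in table.groupby("target_gene", sort=True):
        ratios = [pfaffl_ratio(ExpressionMeasurement(
            gene, str(r.reference_gene), float(r.e_target), float(r.e_ref),
            float(r.dct_target), float(r.dct_ref))) for r in sub.itertuples()]
        summary = summarize_replicates(ratios)
        rows.append({"target_gene": gene, **summary})
    return pd.DataFrame(rows)
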