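"""Per-site differential methylation testing between two groups.

Sites covered by at least `min_coverage` reads in EACH group are tested
with a two-sided Fisher exact test on pooled (methylated, unmethylated)
counts, or a Welch t-test on per-replicate methylation levels. The
two-sided Fisher p-value uses the minimum-likelihood tail definition (sum
of all hypergeometric outcomes no more probable than the observed table),
the convention consistent with published per-site tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

# relative tolerance when comparing table probabilities, as in R fisher.test
_REL_TOL = 1.0 + 1e-7


@dataclass(frozen=True)
class DiffConfig:
    min_coverage: int = 5
    alpha: float = 0.05
    test: str = "auto"              # fisher | ttest | auto
    min_abs_difference: float = 0.0
    rounding: int = 2

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.test not in ("fisher", "ttest", "auto"):
            raise ValueError(f"unknown test {self.test!r}")


@lru_cache(maxsize=100_000)
def fisher_site(x1: int, n1: int, x2: int, n2: int) -> float:
    """Two-sided Fisher exact p-value for methylated counts x1/n1 vs x2/n2.

    Minimum-likelihood method: with margins fixed, sum hypergeometric
    probabilities of every table whose probability does not exceed that of
    the observed table. Computed with scipy's hypergeometric pmf, which is
    log-space stable for large counts.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("group totals must be >= 1")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("methylated counts must satisfy 0 <= x <= n")
    total = n1 + n2
    k = x1 + x2  # methylated margin
    lo, hi = max(0, k - n2), min(k, n1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, total, k, n1)
    p_obs = pmf[x1 - lo]
    p = float(pmf[pmf <= p_obs * _REL_TOL].sum())
    return min(p, 1.0)


def ttest_site(levels1: np.ndarray | list[float],
               levels2: np.ndarray | list[float]) -> tuple[float, float, bool]:
    """Two-sided Welch t-test on per-replicate methylation levels.

    Returns (p_value, degrees_of_freedom, degenerate). A zero-variance,
    zero-difference comparison is degenerate and reported as p = 1.
    """
    a = np.asarray(levels1, dtype=float)
    b = np.asarray(levels2, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicates per group")
    if a.std() == 0 and b.std() == 0:
        return (1.0, float(len(a) + len(b) - 2), True) if a.mean() == b.mean() \
            else (0.0, float(len(a) + len(b) - 2), True)
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.pvalue), float(res.df), False


def run_comparison(calls1: pd.DataFrame, calls2: pd.DataFrame,
                   cfg: DiffConfig | None = None,
                   replicates1: list[pd.DataFrame] | None = None,
                   replicates2: list[pd.DataFrame] | None = None) -> pd.DataFrame:
    """Site-by-site comparison of two pooled call tables.

    A site enters the test only with coverage >= min_coverage in each
    group. Output columns mirror the per-site report format: one row per
    site with totals n1/n2, methylated counts x1/x2, levels m1/m2,
    difference (m2 - m1), p_value, BH q_value, test_used and direction
    (hyper = higher in group 2).

    With test="ttest", per-replicate tables must be supplied; sites lacking
    two replicates with sufficient coverage in either group fall back to
    Fisher on the pooled counts (flagged in test_used).
    """
    cfg = cfg or DiffConfig()
    key = ["contig", "pos", "strand", "context"]
    merged = calls1.merge(calls2, on=key, suffixes=("_1", "_2"))
    merged = merged[(merged["coverage_1"] >= cfg.min_coverage)
                    & (merged["coverage_2"] >= cfg.min_coverage)]
    if len(merged) == 0:
        import warnings
        warnings.warn("no sites pass the per-group coverage filter", stacklevel=2)

    rep_levels = None
    if cfg.test == "ttest":
        if not replicates1 or not replicates2:
            raise ValueError("test='ttest' requires per-replicate call tables")
        rep_levels = (_replicate_level_index(replicates1, cfg.min_coverage),
                      _replicate_level_index(replicates2, cfg.min_coverage))

    rows = []
    for r in merged.itertuples():
        n1, n2 = int(r.coverage_1), int(r.coverage_2)
        x1, x2 = int(r.count_C_1), int(r.count_C_2)
        m1, m2 = x1 / n1, x2 / n2
        site = (r.contig, r.pos, r.strand)
        test_used = "fisher"
        if rep_levels is not None:
            l1 = rep_levels[0].get(site, [])
            l2 = rep_levels[1].get(site, [])
            if len(l1) >= 2 and len(l2) >= 2:
                p, _, _ = ttest_site(l1, l2)
                test_used = "ttest"
            else:
                p = fisher_site(x1, n1, x2, n2)
                test_used = "fisher(fallback)"
        else:
            p = fisher_site(x1, n1, x2, n2)
        diff = m2 - m1
        if abs(diff) < cfg.min_abs_difference:
            continue
        rows.append({
            "contig": r.contig, "start": int(r.pos), "end": int(r.pos) + 1,
            "strand": r.strand, "context": r.context,
            "n1": n1, "n2": n2, "x1": x1, "x2": x2, "m1": m1, "m2": m2,
            "difference": diff, "p_value": p, "test_used": test_used,
            "direction": "hyper" if diff > 0 else ("hypo" if diff < 0 else "none"),
        })
    out = pd.DataFrame(rows, columns=["contig", "start", "end", "strand", "context",
                                      "n1", "n2", "x1", "x2", "m1", "m2",
                                      "difference", "p_value", "test_used", "direction"])
    out["q_value"] = _bh_adjust(out["p_value"].to_numpy()) if len(out) else []
    out["significant"] = out["p_value"] < cfg.alpha
    return out


def summarize_comparison(table: pd.DataFrame, cfg: DiffConfig | None = None) -> pd.DataFrame:
    """Per-context counts of tested and significant sites."""
    cfg = cfg or DiffConfig()
    rows = []
    for ctx, sub in table.groupby("context"):
        sig = int((sub["p_value"] < cfg.alpha).sum())
        rows.append({"context": ctx, "tested": len(sub), "significant": sig,
                     "fraction_significant": sig / len(sub)})
    sig = int((table["p_value"] < cfg.alpha).sum())
    rows.append({"context": "all", "tested": len(table), "significant": sig,
                 "fraction_significant": sig / len(table) if len(table) else float("nan")})
    return pd.DataFrame(rows)


def reconstruct_table(n1: int, n2: int, abs_difference: float,
                      decimals: int = 2) -> tuple[list[tuple[int, int]], bool]:
    """Invert printed (total1, total2, |methylation difference|) columns.

    Enumerates integer (x1, x2) with |x1/n1 - x2/n2| rounding to
    `abs_difference` at the given precision, canonicalized to m1 >= m2 so
    group-swapped mirrors count once. Returns (candidates, unique_flag).
    """
    target = round(abs_difference, decimals)
    out = []
    for x1 in range(n1 + 1):
        for x2 in range(n2 + 1):
            m1, m2 = x1 / n1, x2 / n2
            if m1 < m2:
                continue
            if round(m1 - m2, decimals) == target:
                out.append((x1, x2))
    return out, len(out) == 1


def _replicate_level_index(tables: list[pd.DataFrame], min_cov: int) -> dict:
    idx: dict[tuple, list[float]] = {}
    for t in tables:
        ok = t[t["coverage"] >= min_cov]
        for r in ok.itertuples():
            idx.setdefault((r.contig, r.pos, r.strand), []).append(float(r.level))
    return idx


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out
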