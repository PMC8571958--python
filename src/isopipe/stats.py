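"""Summary statistics: Welch tests from group summaries, composition
percentages, and expression correlation grids.

Trait tables in livestock studies are usually printed as ``mean ± SD``
with per-group n, which is all the Welch unequal-variance t-test needs:

    t  = (m_a - m_b) / sqrt(sd_a^2/n_a + sd_b^2/n_b)
    df = (v_a + v_b)^2 / (v_a^2/(n_a-1) + v_b^2/(n_b-1)),  v_i = sd_i^2/n_i

with a two-sided p from the t distribution.  The fractional df is the
Welch-Satterthwaite approximation; a pooled-variance test is deliberately
not offered.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"{self.label}: n must be >= 2")
        if self.sd < 0:
            raise ValueError(f"{self.label}: sd must be >= 0")


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


def welch_from_summary(a: GroupSummary, b: GroupSummary) -> WelchResult:
    """Welch two-sample t-test from (n, mean, sd) summaries."""
    va = a.sd**2 / a.n
    vb = b.sd**2 / b.n
    se2 = va + vb
    if se2 == 0:
        raise ValueError("both group SDs are zero; t is undefined")
    t = (a.mean - b.mean) / np.sqrt(se2)
    df = se2**2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return WelchResult(float(t), float(df), p)


def welch_from_samples(x, y) -> WelchResult:
    """Welch test on raw samples (scipy), same result container."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    res = sps.ttest_ind(x, y, equal_var=False)
    return WelchResult(float(res.statistic), float(res.df), float(res.pvalue))


def percentage(count: int, total: int) -> float:
    """100*count/total with half-up rounding to two decimals."""
    if total <= 0:
        raise ValueError("total must be > 0")
    if not 0 <= count <= total:
        raise ValueError("count must be within [0, total]")
    frac = Decimal(100) * Decimal(count) / Decimal(total)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


TIERS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_tier(p: float) -> str:
    for cutoff, stars in TIERS:
        if p < cutoff:
            return stars
    return "ns"


def correlation_matrix(
    lnc_expr: pd.DataFrame,
    target_expr: pd.DataFrame,
    add_bh: bool = False,
) -> pd.DataFrame:
    """Pearson correlation grid between two expression matrices.

    Both frames are transcripts x samples with identical sample columns
    (>= 3 samples).  One row per (lncRNA, target) pair with r, the
    two-sided p, and a significance tier (* / ** / *** at 0.05 / 0.01 /
    0.001).  Zero-variance vectors yield NaN r with ``flag="zero_variance"``.
    ``add_bh`` appends a Benjamini-Hochberg adjusted p column (off by
    default; the tiers always use the raw p).
    """
    if list(lnc_expr.columns) != list(target_expr.columns):
        raise ValueError("sample columns must match between matrices")
    if lnc_expr.shape[1] < 3:
        raise ValueError("need >= 3 samples for correlation")
    rows = []
    for lnc_id, x in lnc_expr.iterrows():
        xv = x.to_numpy(dtype=float)
        for tgt_id, y in target_expr.iterrows():
            yv = y.to_numpy(dtype=float)
            if np.ptp(xv) == 0 or np.ptp(yv) == 0:
                rows.append(
                    {
                        "lncrna": lnc_id,
                        "target": tgt_id,
                        "r": np.nan,
                        "p": np.nan,
                        "tier": "ns",
                        "flag": "zero_variance",
                    }
                )
                continue
            r, p = sps.pearsonr(xv, yv)
            rows.append(
                {
                    "lncrna": lnc_id,
                    "target": tgt_id,
                    "r": float(r),
                    "p": float(p),
                    "tier": significance_tier(float(p)),
                    "flag": "",
                }
            )
    df = pd.DataFrame(rows)
    if add_bh:
        mask = df["p"].notna()
        adj = np.full(len(df), np.nan)
        if mask.any():
            adj[mask.to_numpy()] = sps.false_discovery_control(
                df.loc[mask, "p"].to_numpy()
            )
        df["p_bh"] = adj
    return df
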