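"""Group-level inference.

ROI families (%CBV changes, Fisher-Z connectivity, ReHo Z) are compared with
two-way ANOVA (group x region, Type-II sums of squares for unbalanced
cohorts) followed by per-region contrasts corrected with Benjamini-Hochberg
FDR at q = 0.1.  ROI time-courses are compared with a group x time
repeated-measures ANOVA followed by per-timepoint Sidak-adjusted tests.
Pixel-wise t maps are converted to Z maps by probability matching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sstats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TwoWayAnovaResult",
    "two_way_anova",
    "per_roi_group_tests",
    "fdr_correct",
    "rm_anova_sidak",
    "sidak_alpha",
    "t_to_z",
    "one_sample_z_map",
]


@dataclass
class TwoWayAnovaResult:
    table: pd.DataFrame  # rows: group, roi, interaction; columns: F, p, df, sum_sq
    degenerate: bool = False


def two_way_anova(table: pd.DataFrame, value: str = "value") -> TwoWayAnovaResult:
    """Two-way ANOVA with factors ``group`` and ``roi`` (Type-II SS).

    The input is long-form with one value per animal x roi.  Empty cells are
    rejected by name; a layout with (numerically) zero error variance is
    returned flagged degenerate with NaN statistics instead of nonsense F
    values.
    """
    df = table.copy()
    for col in ("group", "roi", value):
        if col not in df.columns:
            raise ValueError(f"table must have a {col!r} column")
    counts = df.groupby(["group", "roi"], sort=True).size()
    full = pd.MultiIndex.from_product(
        [sorted(df["group"].unique()), sorted(df["roi"].unique())], names=["group", "roi"]
    )
    missing = full.difference(counts.index)
    if len(missing):
        raise ValueError(f"empty design cells: {list(missing)}")
    fit = ols(f"{value} ~ C(group) * C(roi)", data=df).fit()
    total_ss = float(((df[value] - df[value].mean()) ** 2).sum())
    if fit.df_resid < 1 or fit.ssr <= max(total_ss, 1.0) * 1e-12:
        out = pd.DataFrame(
            {"sum_sq": np.nan, "df": np.nan, "F": np.nan, "p": np.nan},
            index=["group", "roi", "interaction"],
        )
        return TwoWayAnovaResult(table=out, degenerate=True)
    aov = anova_lm(fit, typ=2)
    out = aov.rename(
        index={"C(group)": "group", "C(roi)": "roi", "C(group):C(roi)": "interaction"},
        columns={"PR(>F)": "p"},
    )
    out = out.loc[["group", "roi", "interaction"], ["sum_sq", "df", "F", "p"]]
    return TwoWayAnovaResult(table=out, degenerate=False)


def per_roi_group_tests(table: pd.DataFrame, value: str = "value") -> pd.DataFrame:
    """Per-ROI two-sample t tests between the two groups (two-sided).

    These are the follow-up comparisons fed to ``fdr_correct``.
    """
    groups = sorted(table["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    rows = []
    for roi, sub in table.groupby("roi", sort=True):
        a = sub.loc[sub["group"] == groups[0], value].to_numpy()
        b = sub.loc[sub["group"] == groups[1], value].to_numpy()
        t, p = sstats.ttest_ind(a, b)
        rows.append(
            {"roi": roi, "mean_a": a.mean(), "mean_b": b.mean(), "t": float(t), "p": float(p)}
        )
    return pd.DataFrame(rows)


def fdr_correct(p_values, q: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up at level ``q``.

    Returns ``(reject, q_values)``; q-values are monotone non-decreasing in p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, qvals, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, qvals


def sidak_alpha(alpha: float, m: int) -> float:
    """Sidak-adjusted per-comparison level: 1 - (1 - alpha)^(1/m)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return 1.0 - (1.0 - alpha) ** (1.0 / m)


def rm_anova_sidak(
    table: pd.DataFrame,
    alpha: float = 0.05,
    value: str = "value",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group x time repeated-measures ANOVA with per-timepoint Sidak tests.

    ``table`` is long-form with columns ``animal``, ``group``, ``time`` and a
    value column: one time-course per animal, all on the same time grid
    (timepoints missing for any animal are dropped listwise with a warning).
    Returns the mixed-ANOVA table and a per-timepoint frame with the group
    contrast, its raw p, the Sidak-adjusted level and the significance flag.
    """
    import warnings

    df = table.copy()
    n_animals = df["animal"].nunique()
    counts = df.groupby("time")["animal"].nunique()
    bad_times = counts[counts < n_animals].index
    if len(bad_times):
        warnings.warn(f"dropping {len(bad_times)} timepoints with missing animals")
        df = df[~df["time"].isin(bad_times)]
    aov = pg.mixed_anova(
        data=df, dv=value, within="time", between="group", subject="animal"
    )
    groups = sorted(df["group"].unique())
    times = np.sort(df["time"].unique())
    a_adj = sidak_alpha(alpha, len(times))
    rows = []
    for t in times:
        sub = df[df["time"] == t]
        a = sub.loc[sub["group"] == groups[0], value].to_numpy()
        b = sub.loc[sub["group"] == groups[1], value].to_numpy()
        tt, p = sstats.ttest_ind(a, b)
        rows.append(
            {
                "time": float(t),
                "diff": float(a.mean() - b.mean()),
                "t": float(tt),
                "p": float(p),
                "alpha_sidak": a_adj,
                "significant": bool(p < a_adj),
            }
        )
    return aov, pd.DataFrame(rows)


def t_to_z(t, df: int):
    """Convert t statistics to Z scores by probability matching.

    Z = Phi^-1(F_t(t; df)), evaluated through the tail that keeps precision,
    so the conversion is sign-preserving and strictly monotone in t.
    """
    t = np.asarray(t, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    z = np.full(t.shape, np.nan)
    finite = np.isfinite(t)
    neg = finite & (t <= 0)
    pos = finite & (t > 0)
    z[neg] = sstats.norm.ppf(sstats.t.cdf(t[neg], df))
    z[pos] = -sstats.norm.ppf(sstats.t.sf(t[pos], df))
    return z if z.shape else float(z)


def one_sample_z_map(
    stack: np.ndarray,
    mask: np.ndarray,
    p_threshold: float = 0.001,
    popmean: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel one-sample t across the first axis, converted to Z.

    Returns ``(z_map, valid_mask, significant_mask)``; zero-variance pixels
    are marked invalid rather than producing infinite statistics.
    """
    stack = np.asarray(stack, dtype=float)
    n = stack.shape[0]
    if n < 3:
        raise ValueError("need at least 3 observations per pixel")
    mean = stack.mean(axis=0) - popmean
    sd = stack.std(axis=0, ddof=1)
    valid = np.asarray(mask, dtype=bool) & (sd > 0) & np.isfinite(sd)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(valid, mean / (sd / np.sqrt(n)), 0.0)
    z = np.where(valid, t_to_z(t, n - 1), 0.0)
    z_crit = sstats.norm.isf(p_threshold / 2.0)
    sig = valid & (np.abs(z) > z_crit)
    return z, valid, sig
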