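"""Temporal binning, within-embryo error bars and group comparisons.

Time-lapse quantities are aggregated in 4.5-min bins in two stages
(domain → embryo → group); the indicative confidence band shown with
means is the mean of within-embryo variances (between-embryo variation
is accounted for in the tests, not displayed). Group comparisons treat
the embryo as the experimental unit: the default backend tests per-bin
embryo means (a pluggable approximation to the full mixed-effects
model with embryo as random intercept, also available via statsmodels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["BinnedSeries", "bin_timeseries", "compare_groups", "ks_two_sample"]

ANALYSIS_WINDOW_MIN = (-18.0, 18.0)
BIN_WIDTH_MIN = 4.5


@dataclass
class BinnedSeries:
    """Binned group series with within-embryo variance error bars."""

    bin_centres: np.ndarray
    embryo_means: pd.DataFrame  # index bin centre, columns embryo ids
    mean: np.ndarray  # across-embryo mean per bin
    within_var: np.ndarray  # mean of within-embryo variances per bin
    n_embryos: np.ndarray
    flags: list[str]

    @property
    def ci(self) -> np.ndarray:
        """Indicative confidence half-width: sqrt(mean within-embryo var)."""
        return np.sqrt(self.within_var)


def _bin_edges(window=ANALYSIS_WINDOW_MIN, width=BIN_WIDTH_MIN):
    n = int(round((window[1] - window[0]) / width))
    return window[0] + np.arange(n + 1) * width


def bin_timeseries(
    values: pd.DataFrame,
    value_col: str,
    bin_width_min: float = BIN_WIDTH_MIN,
    window_min=ANALYSIS_WINDOW_MIN,
) -> BinnedSeries:
    """Two-stage aggregation of per-domain values into time bins.

    ``values`` needs columns ``embryo``, ``time_min`` and ``value_col``.
    Per bin: the mean over each embryo's domains, then the mean over
    embryos; the error band is the mean of within-embryo variances.
    """
    for col in ("embryo", "time_min", value_col):
        if col not in values.columns:
            raise ValueError(f"missing column {col!r}")
    edges = _bin_edges(window_min, bin_width_min)
    centres = (edges[:-1] + edges[1:]) / 2.0
    flags = []
    v = values.copy()
    v["bin"] = pd.cut(v["time_min"], edges, labels=False, include_lowest=True)
    v = v.dropna(subset=["bin"])
    emb_means = v.groupby(["bin", "embryo"])[value_col].mean().unstack("embryo")
    emb_vars = v.groupby(["bin", "embryo"])[value_col].var(ddof=1).unstack("embryo")
    emb_means = emb_means.reindex(range(len(centres)))
    emb_vars = emb_vars.reindex(range(len(centres)))
    mean = emb_means.mean(axis=1).to_numpy()
    within = emb_vars.mean(axis=1).to_numpy()
    n_emb = emb_means.notna().sum(axis=1).to_numpy()
    for i, n in enumerate(n_emb):
        if n == 0:
            flags.append(f"bin {centres[i]:+.2f} min empty")
    if v["embryo"].nunique() == 1:
        flags.append("single embryo: CI degenerates to within-embryo variance")
    emb_means.index = centres
    return BinnedSeries(centres, emb_means, mean, within, n_emb, flags)


def compare_groups(
    a: pd.DataFrame,
    b: pd.DataFrame,
    value_col: str,
    backend: str = "embryo_means",
    alpha: float = 0.05,
    bin_width_min: float = BIN_WIDTH_MIN,
    window_min=ANALYSIS_WINDOW_MIN,
) -> pd.DataFrame:
    """Per-bin group comparison with embryo as the experimental unit.

    ``backend`` is "embryo_means" (Welch t-test on per-embryo bin means;
    the default two-level approximation) or "mixed" (statsmodels MixedLM
    with a random embryo intercept). Returns one row per bin with the
    p-value and a significance flag at ``alpha``.
    """
    for df in (a, b):
        if df["embryo"].nunique() < 2:
            raise ValueError("need >= 2 embryos per group")
    edges = _bin_edges(window_min, bin_width_min)
    centres = (edges[:-1] + edges[1:]) / 2.0
    rows = []
    for i, centre in enumerate(centres):
        lo, hi = edges[i], edges[i + 1]
        sel_a = a[(a["time_min"] >= lo) & (a["time_min"] < hi)]
        sel_b = b[(b["time_min"] >= lo) & (b["time_min"] < hi)]
        p = np.nan
        note = ""
        if sel_a["embryo"].nunique() >= 2 and sel_b["embryo"].nunique() >= 2:
            if backend == "embryo_means":
                ma = sel_a.groupby("embryo")[value_col].mean()
                mb = sel_b.groupby("embryo")[value_col].mean()
                if ma.var(ddof=1) + mb.var(ddof=1) <= 0:
                    note = "degenerate variance"
                else:
                    p = float(sps.ttest_ind(ma, mb, equal_var=False).pvalue)
            elif backend == "mixed":
                import warnings as _warnings

                import statsmodels.formula.api as smf

                d = pd.concat([sel_a.assign(group=0), sel_b.assign(group=1)])
                d = d.rename(columns={value_col: "y"})[["y", "group", "embryo"]].dropna()
                if d["y"].var(ddof=1) <= 0:
                    note = "degenerate variance"
                else:
                    try:
                        with _warnings.catch_warnings():
                            _warnings.simplefilter("ignore")
                            m = smf.mixedlm("y ~ group", d, groups=d["embryo"]).fit(reml=True)
                        p = float(m.pvalues["group"])
                    except Exception:  # singular fits on degenerate bins
                        note = "mixed model failed"
            else:
                raise ValueError(f"unknown backend {backend!r}")
        else:
            note = "insufficient embryos in bin"
        rows.append({"bin_centre_min": centre, "p": p,
                     "significant": bool(p < alpha) if np.isfinite(p) else False,
                     "note": note})
    return pd.DataFrame(rows)


def plot_binned_series(series: BinnedSeries, ylabel: str, path, cumulative_dt=None) -> None:
    """Save a time-course plot of a binned series with its within-embryo
    error band; with ``cumulative_dt`` (minutes per bin) a second panel
    shows the cumulative strain ratio computed from the bin means only."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_panels = 2 if cumulative_dt else 1
    fig, axes = plt.subplots(1, n_panels, figsize=(4.5 * n_panels, 3.2), squeeze=False)
    ax = axes[0, 0]
    ok = ~np.isnan(series.mean)
    ax.errorbar(series.bin_centres[ok], series.mean[ok], yerr=series.ci[ok],
                fmt="o-", capsize=2)
    ax.axhline(0.0, color="0.7", lw=0.8)
    ax.set_xlabel("time (min)")
    ax.set_ylabel(ylabel)
    if cumulative_dt:
        ratio = np.exp(np.nancumsum(np.where(ok, series.mean, 0.0)) * cumulative_dt)
        ax2 = axes[0, 1]
        ax2.plot(series.bin_centres, ratio, "-")
        ax2.axhline(1.0, color="0.7", lw=0.8)
        ax2.set_xlabel("time (min)")
        ax2.set_ylabel("cumulative strain ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and p-value.

    Uses the asymptotic p for adequately sized samples; below n = 3 in
    either sample a warning is raised and the exact p is used.
    """
    import warnings

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    method = "asymp"
    if min(len(a), len(b)) < 3:
        warnings.warn("tiny sample: using exact KS p-value", stacklevel=2)
        method = "exact"
    res = sps.ks_2samp(a, b, method=method)
    return float(res.statistic), float(res.pvalue)
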