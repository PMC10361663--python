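"""Cohort statistics and reporting.

Group comparisons use the two-tailed Mann-Whitney U test (exact
enumeration for small tie-free samples, normal approximation with tie
correction otherwise) and rank correlations use Spearman's rho.  To pool
pole-to-pole profiles from spindles of different lengths, each profile
is rescaled to a common [0, 1] pole-to-pole fraction, interpolated onto
a shared grid, max-normalized per cell, and averaged with a per-point
t-distribution 95% confidence band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

#: significance star codes: threshold -> symbol (scanned in order)
STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))

EXACT_MAX_N = 12  # combined sample size up to which the exact null is used


@dataclass
class GroupComparison:
    """Two-group Mann-Whitney summary."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    method: str
    degenerate: bool = False

    @property
    def stars(self) -> str:
        return star_code(self.p_value)


@dataclass
class CorrelationResult:
    """Spearman rank correlation."""

    rho: float
    p_value: float
    n: int


@dataclass
class AveragedProfile:
    """Size-normalized mean profile with a 95% confidence band."""

    positions: np.ndarray  # pole-to-pole fraction in [0, 1]
    per_cell: np.ndarray  # (n_cells, grid_n)
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_cells: int


def star_code(p: float) -> str:
    """Significance stars: * <=0.05, ** <=0.01, *** <=0.001, **** <=0.0001."""
    for thr, sym in STAR_THRESHOLDS:
        if p <= thr:
            return sym
    return "ns"


def mann_whitney(a, b, label_a: str = "a", label_b: str = "b") -> GroupComparison:
    """Two-tailed Mann-Whitney U comparison of two independent samples.

    Uses the exact null distribution when the combined sample size is at
    most 12 and there are no ties across groups, otherwise the normal
    approximation with tie correction.  Identical multisets short-circuit
    to p = 1 with the ``degenerate`` flag set.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError(f"need >= 3 values per group, got {len(a)} and {len(b)}")
    base = dict(label_a=label_a, label_b=label_b, n_a=len(a), n_b=len(b),
                mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
                mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)))
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return GroupComparison(u_statistic=len(a) * len(b) / 2.0, p_value=1.0,
                               method="degenerate", degenerate=True, **base)
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= EXACT_MAX_N and not has_ties:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        method = "asymptotic"
    return GroupComparison(u_statistic=float(res.statistic),
                           p_value=float(min(res.pvalue, 1.0)), method=method, **base)


def spearman(x, y) -> CorrelationResult:
    """Two-tailed Spearman rank correlation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 4:
        raise ValueError(f"need >= 4 pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: Spearman correlation undefined")
    res = sps.spearmanr(x, y)
    p = float(res.pvalue) if math.isfinite(res.pvalue) else 1.0
    return CorrelationResult(float(res.statistic), p, len(x))


def average_profiles(profiles: list, grid_n: int = 100,
                     max_normalize: bool = True) -> AveragedProfile:
    """Average pole-to-pole profiles across cells of different spindle sizes.

    Each profile's positions are rescaled to span [0, 1], linearly
    interpolated to a common ``grid_n``-point grid and (by default)
    divided by its own maximum; the band is the per-point t-based 95% CI.
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 profiles to average")
    grid = np.linspace(0.0, 1.0, grid_n)
    rows = []
    for i, p in enumerate(profiles):
        pos, vals = p.positions, p.intensities
        if len(pos) < 4:
            raise ValueError(f"profile {i} has < 4 samples; rejected")
        span = pos[-1] - pos[0]
        frac = (pos - pos[0]) / span
        v = np.interp(grid, frac, vals)
        if max_normalize:
            vmax = v.max()
            if vmax <= 0:
                raise ValueError(f"profile {i} has non-positive maximum; rejected")
            v = v / vmax
        rows.append(v)
    per_cell = np.vstack(rows)
    n = per_cell.shape[0]
    mean = per_cell.mean(axis=0)
    sem = per_cell.std(axis=0, ddof=1) / math.sqrt(n)
    t_crit = float(sps.t.ppf(0.975, n - 1))
    return AveragedProfile(grid, per_cell, mean, mean - t_crit * sem,
                           mean + t_crit * sem, n)


# ---------------------------------------------------------------------------
# reporting


def summarize_conditions(df: pd.DataFrame, value_col: str,
                         group_col: str = "condition") -> pd.DataFrame:
    """Per-condition mean +/- sd and n of one measured quantity."""
    _require_columns(df, [group_col, value_col])
    rows = []
    for name, grp in df.groupby(group_col, sort=True):
        vals = grp[value_col].to_numpy(float)
        rows.append({group_col: name, "n": len(vals), "mean": float(np.mean(vals)),
                     "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0})
    return pd.DataFrame(rows)


def compare_conditions(df: pd.DataFrame, value_col: str,
                       group_col: str = "condition") -> pd.DataFrame:
    """All pairwise Mann-Whitney comparisons with star codes.

    With a single condition an empty table (with the right columns) is
    returned.
    """
    _require_columns(df, [group_col, value_col])
    names = sorted(df[group_col].unique())
    rows = []
    for i, na in enumerate(names):
        for nb in names[i + 1:]:
            a = df.loc[df[group_col] == na, value_col].to_numpy(float)
            b = df.loc[df[group_col] == nb, value_col].to_numpy(float)
            cmp = mann_whitney(a, b, str(na), str(nb))
            rows.append({
                "group_a": na, "group_b": nb, "n_a": cmp.n_a, "n_b": cmp.n_b,
                "mean_a": cmp.mean_a, "sd_a": cmp.sd_a,
                "mean_b": cmp.mean_b, "sd_b": cmp.sd_b,
                "U": cmp.u_statistic, "p_value": cmp.p_value,
                "stars": cmp.stars, "method": cmp.method,
            })
    columns = ["group_a", "group_b", "n_a", "n_b", "mean_a", "sd_a",
               "mean_b", "sd_b", "U", "p_value", "stars", "method"]
    return pd.DataFrame(rows, columns=columns)


def report(measurements: pd.DataFrame, out_dir, value_col: str = "value",
           group_col: str = "condition", make_plots: bool = True) -> dict:
    """Write summary and comparison CSVs (and simple plots) for a cohort.

    ``measurements`` is tidy: one row per cell with ``group_col`` and
    ``value_col`` (extra columns pass through untouched).  Returns the
    paths written.
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _require_columns(measurements, [group_col, value_col])

    summary = summarize_conditions(measurements, value_col, group_col)
    comparisons = compare_conditions(measurements, value_col, group_col)
    paths = {
        "summary": out_dir / "summary.csv",
        "comparisons": out_dir / "comparisons.csv",
    }
    summary.to_csv(paths["summary"], index=False)
    comparisons.to_csv(paths["comparisons"], index=False)

    if make_plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 3))
        names = summary[group_col].tolist()
        for i, name in enumerate(names):
            vals = measurements.loc[measurements[group_col] == name, value_col]
            ax.scatter(np.full(len(vals), i), vals, s=12, alpha=0.6)
        ax.bar(range(len(names)), summary["mean"], yerr=summary["sd"],
               fill=False, capsize=4)
        ax.set_xticks(range(len(names)), [str(n) for n in names])
        ax.set_ylabel(value_col)
        fig.tight_layout()
        paths["plot"] = out_dir / "conditions.png"
        fig.savefig(paths["plot"], dpi=120)
        plt.close(fig)
    return paths


def plot_traces(traces: dict, out_path, title: str = "") -> None:
    """Mean +/- sd band plot of a set of normalized traces per condition.

    ``traces`` maps condition name -> (times, array of per-cell traces).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 3))
    for name, (times, arr) in traces.items():
        arr = np.asarray(arr, float)
        mean = arr.mean(axis=0)
        sd = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros_like(mean)
        ax.plot(times, mean, label=str(name))
        ax.fill_between(times, mean - sd, mean + sd, alpha=0.25)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("normalized intensity")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def _require_columns(df: pd.DataFrame, cols: list) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
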