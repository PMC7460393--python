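"""Cluster characterization: representative curves, fit errors, statistics.

Each cluster is summarized by its representative curve (the pointwise
mean of the member smoothed curves, in litres) and compared with the
parametric model fits through two errors:

* ``eps_f`` — RMSE (L) between the fitted model curve and the cluster's
  representative curve;
* ``eps_c`` — the mean, over cluster members, of the RMSE between the
  Z-normalized member curve and the Z-normalized model curve (unitless;
  Z-transforming both sides makes this a pure shape comparison and makes
  it invariant to positive affine rescaling of a member).

Group comparisons across clusters use one-way ANOVA followed by Fisher's
(unprotected) LSD with a compact letter display: clusters sharing no
letter differ at the chosen alpha. Significance is declared at p < 0.05
and 0.05 <= p < 0.1 is flagged as a trend.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lc_models import LCParams
from .preprocess import DIM_GRID, CurveMatrix, DegenerateCurveError, znormalize

__all__ = [
    "ClusterProfile",
    "FitErrors",
    "GroupComparison",
    "representative_curve",
    "epsilon_f",
    "epsilon_c",
    "observed_peak",
    "anova_oneway",
    "fisher_lsd_letters",
    "cluster_summary",
    "summary_table",
]


@dataclass
class ClusterProfile:
    """Per-cluster curves and observed per-member peak features."""

    cluster: int | str
    n: int
    grid: np.ndarray
    representative: np.ndarray
    member_peak_yield: np.ndarray
    member_peak_dim: np.ndarray
    parities: list[int]


@dataclass
class FitErrors:
    eps_f: float
    eps_c: float
    n_members_used: int


@dataclass
class GroupComparison:
    """One summary variable compared across clusters."""

    variable: str
    clusters: list
    ns: list[int]
    means: list[float]
    ses: list[float]
    pooled_se: float
    total_mean: float
    total_se: float
    F: float
    p: float
    letters: list[str]
    trend: bool


def representative_curve(members) -> np.ndarray:
    """Pointwise mean of the member curves (the cluster representative)."""
    M = np.atleast_2d(np.asarray(members, dtype=float))
    if M.shape[0] < 1 or M.size == 0:
        raise ValueError("representative_curve needs at least one member")
    return M.mean(axis=0)


def _rmse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((a - b) ** 2)))


def epsilon_f(fit: LCParams, representative, grid=None) -> float:
    """RMSE (L) between the fitted model curve and the representative."""
    grid = DIM_GRID if grid is None else np.asarray(grid)
    return _rmse(fit.curve(grid), np.asarray(representative, dtype=float))


def epsilon_c(fit: LCParams, members, grid=None) -> FitErrors | float:
    """Mean Z-space RMSE between the model curve and each member curve.

    Both the member and the model curve are Z-normalized before the RMSE,
    so the statistic compares shapes only. Constant (degenerate) members
    are skipped with a warning. Returns the scalar mean.
    """
    grid = DIM_GRID if grid is None else np.asarray(grid)
    M = np.atleast_2d(np.asarray(members, dtype=float))
    z_model = znormalize(fit.curve(grid))
    vals = []
    for i, row in enumerate(M):
        try:
            vals.append(_rmse(znormalize(row), z_model))
        except DegenerateCurveError:
            warnings.warn(f"member {i} is constant; skipped in eps_c", stacklevel=2)
    if not vals:
        raise ValueError("no member with positive variance for eps_c")
    return float(np.mean(vals))


def observed_peak(curve, grid=None) -> tuple[float, int]:
    """Maximum of a smoothed curve and the DIM where it occurs.

    Ties resolve to the earliest DIM.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.size == 0:
        raise ValueError("empty curve")
    grid = DIM_GRID if grid is None else np.asarray(grid)
    i = int(np.argmax(curve))
    return float(curve[i]), int(grid[i])


def _ss_decomposition(groups: list[np.ndarray]):
    ns = np.array([len(g) for g in groups])
    means = np.array([g.mean() for g in groups])
    grand = np.concatenate(groups).mean()
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    df1 = len(groups) - 1
    df2 = int(ns.sum()) - len(groups)
    return ssb, ssw, df1, df2


def anova_oneway(groups) -> tuple[float, float]:
    """One-way fixed-effects ANOVA: F = MS_between / MS_within, upper-tail p.

    Degenerate conventions: zero within-group variance with unequal means
    gives ``(inf, 0.0)``; all values identical gives ``(0.0, 1.0)``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("anova_oneway needs >= 2 groups with >= 2 values each")
    ssb, ssw, df1, df2 = _ss_decomposition(groups)
    if ssw == 0.0:
        return (float("inf"), 0.0) if ssb > 0.0 else (0.0, 1.0)
    F = (ssb / df1) / (ssw / df2)
    return float(F), float(stats.f.sf(F, df1, df2))


def fisher_lsd_letters(groups, alpha: float = 0.05) -> list[str]:
    """Compact letter display from Fisher's LSD pairwise tests.

    Two groups differ when ``|mean_i - mean_j|`` exceeds
    ``t_{1-alpha/2, df_within} * sqrt(MS_within * (1/n_i + 1/n_j))``.
    Letters are built by insert-and-absorb over groups sorted by
    descending mean, so groups share a letter iff their pairwise test is
    non-significant.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    g = len(groups)
    if g == 1:
        return ["a"]
    if any(len(x) < 2 for x in groups):
        raise ValueError("each group needs >= 2 values")
    _, ssw, _, df2 = _ss_decomposition(groups)
    ns = [len(x) for x in groups]
    means = [float(x.mean()) for x in groups]
    msw = ssw / df2
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df2)

    def differ(i: int, j: int) -> bool:
        diff = abs(means[i] - means[j])
        if msw == 0.0:
            return diff > 0.0
        lsd = tcrit * np.sqrt(msw * (1.0 / ns[i] + 1.0 / ns[j]))
        return diff > lsd

    # insert-and-absorb: start from one letter holding everyone, split on
    # each significant pair, drop letter-sets contained in another
    letters: list[set[int]] = [set(range(g))]
    for i in range(g):
        for j in range(i + 1, g):
            if not differ(i, j):
                continue
            for s in [s for s in letters if i in s and j in s]:
                letters.remove(s)
                letters.extend([s - {i}, s - {j}])
            letters = [
                s for s in letters
                if s and not any(s < other for other in letters if other is not s)
            ]
    # dedupe while keeping one copy of identical sets
    unique: list[set[int]] = []
    for s in letters:
        if s not in unique:
            unique.append(s)
    rank = sorted(range(g), key=lambda i: -means[i])
    pos = {grp: r for r, grp in enumerate(rank)}
    unique.sort(key=lambda s: min(pos[i] for i in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = ["" for _ in range(g)]
    for letter, s in zip(alphabet, unique):
        for i in s:
            out[i] += letter
    return ["".join(sorted(s)) for s in out]


def cluster_profiles(matrix: CurveMatrix, labels) -> dict:
    """Build a :class:`ClusterProfile` for every cluster label."""
    labels = np.asarray(labels)
    profiles = {}
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        smoothed = matrix.smoothed[idx]
        peaks = [observed_peak(row, matrix.grid) for row in smoothed]
        profiles[lab] = ClusterProfile(
            cluster=lab,
            n=len(idx),
            grid=matrix.grid,
            representative=representative_curve(smoothed),
            member_peak_yield=np.array([p[0] for p in peaks]),
            member_peak_dim=np.array([float(p[1]) for p in peaks]),
            parities=[matrix.parities[i] for i in idx],
        )
    return profiles


def cluster_summary(matrix: CurveMatrix, labels, alpha: float = 0.05) -> list[GroupComparison]:
    """Descriptive per-cluster statistics with ANOVA and LSD letters.

    Variables: parity, mean daily milk yield (L/day), total milk yield
    over DIM 10-280 (L, sum of interpolated daily yields), observed peak
    DIM (days) and observed peak yield (L) of the smoothed member curves.
    Per-cluster SE is the sample SD divided by sqrt(n); the pooled SE is
    ``sqrt(MS_within * mean_i(1/n_i))``. Clusters of size 1 are reported
    but excluded from the SE-based tests.
    """
    labels = np.asarray(labels)
    cluster_ids = list(np.unique(labels))
    per_member = {
        "parity": np.asarray(matrix.parities, dtype=float),
        "daily_my_l": matrix.raw.mean(axis=1),
        "total_my_l": matrix.raw.sum(axis=1),
        "peak_dim_days": np.array(
            [float(observed_peak(r, matrix.grid)[1]) for r in matrix.smoothed]
        ),
        "peak_my_l": np.array(
            [observed_peak(r, matrix.grid)[0] for r in matrix.smoothed]
        ),
    }
    out: list[GroupComparison] = []
    for var, values in per_member.items():
        groups = [values[labels == c] for c in cluster_ids]
        ns = [len(g) for g in groups]
        means = [float(g.mean()) for g in groups]
        ses = [
            float(g.std(ddof=1) / np.sqrt(len(g))) if len(g) > 1 else float("nan")
            for g in groups
        ]
        testable = [g for g in groups if len(g) > 1]
        if len(testable) >= 2:
            F, p = anova_oneway(testable)
            test_letters = fisher_lsd_letters(testable, alpha=alpha)
            _, ssw, _, df2 = _ss_decomposition(testable)
            msw = ssw / df2 if df2 > 0 else float("nan")
            pooled_se = float(
                np.sqrt(msw * np.mean([1.0 / len(g) for g in testable]))
            )
            letters, it = [], iter(test_letters)
            for g in groups:
                letters.append(next(it) if len(g) > 1 else "")
        else:
            F, p, pooled_se = float("nan"), float("nan"), float("nan")
            letters = ["" for _ in groups]
        out.append(
            GroupComparison(
                variable=var,
                clusters=cluster_ids,
                ns=ns,
                means=means,
                ses=ses,
                pooled_se=pooled_se,
                total_mean=float(values.mean()),
                total_se=float(values.std(ddof=1) / np.sqrt(len(values)))
                if len(values) > 1
                else float("nan"),
                F=F,
                p=p,
                letters=letters,
                trend=bool(0.05 <= p < 0.1) if np.isfinite(p) else False,
            )
        )
    return out


def summary_table(comparisons: list[GroupComparison]) -> pd.DataFrame:
    """Tidy DataFrame view of :func:`cluster_summary` (one row per
    variable x cluster, plus a 'total' row per variable)."""
    rows = []
    for comp in comparisons:
        for c, n, m, se, letter in zip(
            comp.clusters, comp.ns, comp.means, comp.ses, comp.letters
        ):
            rows.append(
                {
                    "variable": comp.variable,
                    "cluster": c,
                    "n": n,
                    "mean": m,
                    "se": se,
                    "letters": letter,
                    "F": comp.F,
                    "p": comp.p,
                    "pooled_se": comp.pooled_se,
                    "trend": comp.trend,
                }
            )
        rows.append(
            {
                "variable": comp.variable,
                "cluster": "total",
                "n": sum(comp.ns),
                "mean": comp.total_mean,
                "se": comp.total_se,
                "letters": "",
                "F": comp.F,
                "p": comp.p,
                "pooled_se": comp.pooled_se,
                "trend": comp.trend,
            }
        )
    return pd.DataFrame(rows)
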