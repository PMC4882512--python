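"""Population-level statistics for per-track mean-speed distributions.

Implements the statistical layer used to compare experimental groups:
quantiles under one fixed convention, a quantile-regression-style group
contrast with bootstrap uncertainty, two-sample t tests (from raw values and
from printed summary statistics), Pearson chi-square for contingency tables,
a two-factor mixed repeated-measures ANOVA, and the fast-mover percentage
with per-cell-line aggregation.

Quantile convention
-------------------
Throughout the package, the τ-quantile of a sample is defined as the
minimiser of the asymmetric check loss Σ ρ_τ(x_i − q); when the minimiser is
an interval (nτ integral), the midpoint of that interval is returned. This
one convention is used for percentile reporting, the fast-speed threshold
calibration, and the group contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupTestResult",
    "SpeedPopulation",
    "check_loss_quantile",
    "speed_percentiles",
    "quantile_group_contrast",
    "t_from_summary",
    "t_from_values",
    "chi_square_table",
    "mixed_rm_anova",
    "percent_fast",
]


@dataclass
class GroupTestResult:
    """Outcome of a two-group comparison.

    ``estimate`` is the effect size on the measurement scale (difference of
    means, quantile difference, ...); ``ci95`` is its 95% confidence
    interval. ``df`` may be a single value or an (effect, error) pair.
    """

    statistic: float
    df: float | tuple
    p: float
    estimate: float = np.nan
    se: float = np.nan
    ci95: tuple = (np.nan, np.nan)
    note: str = ""

    def __post_init__(self) -> None:
        if not np.isnan(self.p) and not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")


@dataclass
class SpeedPopulation:
    """Pooled per-track mean speeds for one experimental group."""

    group: str
    speeds: np.ndarray
    cell_line_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.speeds = np.asarray(self.speeds, dtype=float)
        if np.any(self.speeds < 0):
            raise ValueError("speeds must be non-negative")
        if self.cell_line_ids is not None:
            self.cell_line_ids = np.asarray(self.cell_line_ids)
            if len(self.cell_line_ids) != len(self.speeds):
                raise ValueError("cell_line_ids must parallel speeds")

    def __len__(self) -> int:
        return len(self.speeds)


def check_loss_quantile(values: np.ndarray, tau: float) -> float:
    """τ-quantile as the check-loss minimiser, midpoint rule for ties.

    For a sorted sample x_(1) ≤ ... ≤ x_(n): if nτ is an integer k in
    (0, n), every q in [x_(k), x_(k+1)] minimises the loss and the midpoint
    is returned; otherwise the unique minimiser x_(⌈nτ⌉) is returned.
    """
    values = np.sort(np.asarray(values, dtype=float))
    n = len(values)
    if n == 0:
        raise ValueError("empty sample")
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie in (0, 1)")
    h = n * tau
    k = int(round(h))
    if abs(h - k) < 1e-9 * max(n, 1) and 0 < k < n:
        return 0.5 * (values[k - 1] + values[k])
    return float(values[int(np.ceil(h)) - 1])


def speed_percentiles(pop: SpeedPopulation, taus) -> np.ndarray:
    """Per-τ percentiles of the pooled speed distribution (non-decreasing)."""
    if len(pop) == 0:
        raise ValueError("empty population")
    return np.array([check_loss_quantile(pop.speeds, t) for t in taus])


def quantile_group_contrast(
    control: SpeedPopulation,
    patient: SpeedPopulation,
    taus,
    n_boot: int = 1000,
    seed: int = 0,
) -> list[GroupTestResult]:
    """Quantile-regression group contrast at each τ.

    With a single binary group covariate, the check-loss-minimising group
    coefficient equals the difference of the two groups' τ-quantiles
    (patient − control), which is computed directly. Standard errors and 95%
    CIs come from a case-resampling bootstrap within each group; two-sided p
    from the normal approximation of the bootstrap distribution.
    """
    if len(control) == 0 or len(patient) == 0:
        raise ValueError("both populations must be non-empty")
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200")
    taus = list(taus)
    rng = np.random.default_rng(seed)
    nc, npat = len(control), len(patient)
    boot = np.empty((n_boot, len(taus)))
    for b in range(n_boot):
        cs = control.speeds[rng.integers(0, nc, nc)]
        ps = patient.speeds[rng.integers(0, npat, npat)]
        for j, tau in enumerate(taus):
            boot[b, j] = check_loss_quantile(ps, tau) - check_loss_quantile(cs, tau)
    results = []
    for j, tau in enumerate(taus):
        est = check_loss_quantile(patient.speeds, tau) - check_loss_quantile(control.speeds, tau)
        se = float(np.std(boot[:, j], ddof=1))
        note = ""
        if se == 0.0:
            note = "degenerate bootstrap (all resamples tied)"
            p = 1.0 if est == 0 else 0.0
            z = np.inf if est != 0 else 0.0
        else:
            z = est / se
            p = float(2 * sps.norm.sf(abs(z)))
        lo, hi = np.quantile(boot[:, j], [0.025, 0.975])
        results.append(
            GroupTestResult(
                statistic=float(z), df=np.nan, p=p, estimate=float(est), se=se,
                ci95=(float(lo), float(hi)), note=note,
            )
        )
    return results


def _t_result(t: float, df: float, estimate: float, se: float) -> GroupTestResult:
    p = float(2 * sps.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    tcrit = sps.t.ppf(0.975, df)
    return GroupTestResult(
        statistic=float(t), df=float(df), p=p, estimate=float(estimate), se=float(se),
        ci95=(float(estimate - tcrit * se), float(estimate + tcrit * se)),
    )


def t_from_summary(
    mean1: float, sem1: float, n1: int, mean2: float, sem2: float, n2: int
) -> GroupTestResult:
    """Unpaired two-sample t test from published mean ± SEM summaries.

    t = (mean1 − mean2) / sqrt(sem1² + sem2²) with df = n1 + n2 − 2 (the
    Student convention; at n = 5 + 5 this gives df = 8).
    """
    if sem1 <= 0 or sem2 <= 0:
        raise ValueError("SEMs must be strictly positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    se = float(np.sqrt(sem1**2 + sem2**2))
    t = (mean1 - mean2) / se
    return _t_result(t, n1 + n2 - 2, mean1 - mean2, se)


def t_from_values(group1, group2) -> GroupTestResult:
    """Classical pooled-variance two-sample t test on raw values."""
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    n1, n2 = len(g1), len(g2)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 values per group")
    v1, v2 = g1.var(ddof=1), g2.var(ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    diff = g1.mean() - g2.mean()
    if sp2 == 0.0:
        res = GroupTestResult(
            statistic=np.inf if diff != 0 else 0.0,
            df=float(n1 + n2 - 2),
            p=0.0 if diff != 0 else 1.0,
            estimate=float(diff),
            se=0.0,
            ci95=(float(diff), float(diff)),
            note="zero variance in both groups",
        )
        return res
    se = float(np.sqrt(sp2 * (1 / n1 + 1 / n2)))
    return _t_result(diff / se, n1 + n2 - 2, diff, se)


def chi_square_table(counts) -> GroupTestResult:
    """Pearson chi-square test of independence on an r × c count table."""
    obs = np.asarray(counts, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("every row and column must have a positive total")
    expected = np.outer(rows, cols) / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    res = GroupTestResult(statistic=stat, df=float(df), p=float(sps.chi2.sf(stat, df)))
    res.expected = expected
    return res


def mixed_rm_anova(table: pd.DataFrame, between: dict) -> dict:
    """Two-factor mixed repeated-measures ANOVA.

    Parameters
    ----------
    table : DataFrame
        Wide table: rows = subjects (cell lines), columns = within-subject
        conditions, every subject measured in every condition.
    between : mapping subject -> group label
        Between-subjects factor (e.g. control vs patient).

    Returns a dict with F statistics and (effect, error) df pairs for the
    between-subjects main effect (error = subjects within groups), the
    within-subject condition main effect, and the group × condition
    interaction (error = condition × subjects within groups).
    """
    groups = pd.Series({s: between[s] for s in table.index})
    counts = groups.value_counts()
    if (counts < 2).any():
        raise ValueError("need at least 2 subjects per group")
    if table.isna().any().any():
        raise ValueError("unbalanced design: every subject needs every condition")
    sizes = {
        g: len(table.loc[groups[groups == g].index]) for g in counts.index
    }
    if len(set(sizes.values())) != 1:
        raise ValueError("unbalanced design: unequal group sizes")

    vals = table.to_numpy(dtype=float)
    n_subj, n_cond = vals.shape
    n_groups = counts.size
    grand = vals.mean()

    subj_means = vals.mean(axis=1)
    cond_means = vals.mean(axis=0)
    group_of = groups.to_numpy()
    glabels = list(counts.index)
    gmask = {g: group_of == g for g in glabels}
    group_means = {g: vals[gmask[g]].mean() for g in glabels}
    gc_means = {g: vals[gmask[g]].mean(axis=0) for g in glabels}

    ss_group = n_cond * sum(gmask[g].sum() * (group_means[g] - grand) ** 2 for g in glabels)
    ss_subj_within = n_cond * sum(
        ((subj_means[gmask[g]] - group_means[g]) ** 2).sum() for g in glabels
    )
    ss_cond = n_subj * ((cond_means - grand) ** 2).sum()
    ss_inter = sum(
        gmask[g].sum() * ((gc_means[g] - cond_means - group_means[g] + grand) ** 2).sum()
        for g in glabels
    )
    ss_total = ((vals - grand) ** 2).sum()
    ss_resid = ss_total - ss_group - ss_subj_within - ss_cond - ss_inter

    df_group = n_groups - 1
    df_subj = n_subj - n_groups
    df_cond = n_cond - 1
    df_inter = df_group * df_cond
    df_resid = df_subj * df_cond

    def _f(ss_eff, df_eff, ss_err, df_err):
        ms_eff = ss_eff / df_eff if df_eff else 0.0
        ms_err = ss_err / df_err if df_err else 0.0
        if ms_err == 0.0:
            return 0.0, 1.0  # degenerate (all values equal): report F = 0
        f = ms_eff / ms_err
        return float(f), float(sps.f.sf(f, df_eff, df_err))

    f_group, p_group = _f(ss_group, df_group, ss_subj_within, df_subj)
    f_cond, p_cond = _f(ss_cond, df_cond, ss_resid, df_resid)
    f_inter, p_inter = _f(ss_inter, df_inter, ss_resid, df_resid)
    return {
        "group": {"F": f_group, "df": (df_group, df_subj), "p": p_group, "ss": ss_group},
        "condition": {"F": f_cond, "df": (df_cond, df_resid), "p": p_cond, "ss": ss_cond},
        "interaction": {"F": f_inter, "df": (df_inter, df_resid), "p": p_inter, "ss": ss_inter},
        "ss_subjects_within": ss_subj_within,
        "ss_residual": ss_resid,
    }


def percent_fast(pop: SpeedPopulation, fast_threshold: float = 0.14) -> dict:
    """Overall and per-cell-line percentage of fast movers.

    A track is fast iff its mean speed strictly exceeds ``fast_threshold``.
    The per-line values give the line-level mean ± SEM, matching analyses
    where the cell line is the unit of replication.
    """
    if len(pop) == 0:
        raise ValueError("empty population")
    fast = pop.speeds > fast_threshold
    out = {"overall_percent": 100.0 * fast.mean(), "n_tracks": len(pop)}
    if pop.cell_line_ids is not None:
        per_line = {}
        for line in pd.unique(pop.cell_line_ids):
            mask = pop.cell_line_ids == line
            if mask.sum() == 0:
                raise ValueError(f"cell line {line!r} has zero tracks")
            per_line[line] = 100.0 * fast[mask].mean()
        vals = np.array(list(per_line.values()))
        out["per_line_percent"] = per_line
        out["line_mean"] = float(vals.mean())
        out["line_sem"] = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
    return out
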