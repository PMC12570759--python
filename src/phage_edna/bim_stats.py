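"""Statistics for bacteriophage-insensitive mutant (BIM) plate assays.

A BIM assay challenges *S. thermophilus* with phage under some condition
(untreated lysate, DNase-treated, buffer-only control, purified phage,
DNA-supplemented ...) and counts surviving colonies.  Day-to-day culture
variability is removed by normalising each plate to the mean count of
that day's reference condition and reporting log2 fold changes.

The decision procedure for comparing conditions follows standard
heteroscedasticity-aware practice: Bartlett's test on the groups; if the
variances are compatible *and* the groups are exactly equal-sized, a
classical one-way ANOVA with Tukey's HSD post hoc; otherwise Welch's
ANOVA with the Games-Howell post hoc.  By default only comparisons
against the designated control condition are reported, and sweeps over
the multiplicity of infection (MOI) are analysed independently per MOI
bin.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .uncertainty import UValue

__all__ = [
    "PairwiseResult",
    "AnalysisReport",
    "DegenerateVarianceError",
    "MissingBaselineError",
    "daily_baseline",
    "log2_fold_change",
    "bartlett_test",
    "welch_anova",
    "games_howell",
    "anova_tukey",
    "select_and_run",
    "per_moi_analysis",
    "percent_change",
    "read_plate_counts",
]

PLATE_COLUMNS = ["day_id", "lysate_id", "condition", "moi", "cfu"]

#: Pseudo-count substituted for zero CFU before the log2 transform so
#: that empty plates stay in the analysis (they are flagged).
ZERO_CFU_PSEUDOCOUNT = 0.5


class DegenerateVarianceError(ValueError):
    """A group has zero variance, so variance-weighted tests are undefined."""


class MissingBaselineError(ValueError):
    """One or more days lack an observation of the reference condition."""


# ---------------------------------------------------------------------------
# Normalisation
# ---------------------------------------------------------------------------


def read_plate_counts(path) -> pd.DataFrame:
    """Read a plate-count CSV (`day_id,lysate_id,condition,moi,cfu`)."""
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate-count table is missing columns: {missing}")
    if (df["cfu"] < 0).any() or (df["moi"] < 0).any():
        raise ValueError("cfu and moi must be non-negative")
    return df


def daily_baseline(
    observations: pd.DataFrame, reference_condition: str = "untreated"
) -> pd.Series:
    """Per-day baseline: the arithmetic mean CFU of the reference condition.

    Every day present in ``observations`` must have at least one plate of
    the reference condition; baselines are never pooled across days.
    """
    ref = observations[observations["condition"] == reference_condition]
    baselines = ref.groupby("day_id")["cfu"].mean()
    missing = sorted(set(observations["day_id"]) - set(baselines.index))
    if missing:
        raise MissingBaselineError(
            f"days without any {reference_condition!r} observation: {missing}"
        )
    return baselines


def log2_fold_change(
    observations: pd.DataFrame, baselines: Mapping[str, float]
) -> pd.DataFrame:
    """log2(cfu / day baseline) per plate.

    Zero counts are replaced by ``ZERO_CFU_PSEUDOCOUNT`` and flagged in
    the ``zero_flag`` column rather than dropped.
    """
    baselines = pd.Series(baselines)
    if (baselines <= 0).any():
        bad = baselines[baselines <= 0].index.tolist()
        raise ValueError(f"baselines must be positive; offending days: {bad}")
    out = observations.copy()
    base = out["day_id"].map(baselines)
    if base.isna().any():
        missing = sorted(out.loc[base.isna(), "day_id"].unique())
        raise MissingBaselineError(f"no baseline for days: {missing}")
    counts = out["cfu"].astype(float)
    out["zero_flag"] = counts == 0
    counts = counts.where(counts > 0, ZERO_CFU_PSEUDOCOUNT)
    out["baseline"] = base
    out["log2fc"] = np.log2(counts / base)
    return out


# ---------------------------------------------------------------------------
# Omnibus and post-hoc tests
# ---------------------------------------------------------------------------


def _check_groups(groups: Sequence[np.ndarray], min_n: int = 2) -> list[np.ndarray]:
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for i, g in enumerate(arrays):
        if g.size < min_n:
            raise ValueError(f"group {i} has n={g.size} < {min_n} observations")
    return arrays


def bartlett_test(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Bartlett's test of homoscedasticity (chi-square, k-1 df)."""
    arrays = _check_groups(groups)
    stat, p = stats.bartlett(*arrays)
    return float(stat), float(p)


def welch_anova(groups: Sequence[np.ndarray]) -> tuple[float, float, float, float]:
    """Welch's heteroscedastic one-way ANOVA.

    Returns ``(F, df1, df2, p)`` with the Welch-Satterthwaite denominator
    degrees of freedom.  Raises :class:`DegenerateVarianceError` if any
    group has zero variance (variance weights would be infinite).
    """
    arrays = _check_groups(groups)
    k = len(arrays)
    n = np.array([g.size for g in arrays], dtype=float)
    m = np.array([g.mean() for g in arrays])
    v = np.array([g.var(ddof=1) for g in arrays])
    if np.any(v == 0):
        raise DegenerateVarianceError(
            "a group has zero variance; Welch weights are undefined"
        )
    w = n / v
    w_sum = w.sum()
    grand = (w * m).sum() / w_sum
    a = ((w * (m - grand) ** 2).sum()) / (k - 1)
    lam = (((1 - w / w_sum) ** 2) / (n - 1)).sum()
    b = 1 + 2.0 * (k - 2) / (k**2 - 1) * lam
    f_stat = a / b
    df1 = k - 1
    df2 = (k**2 - 1) / (3.0 * lam)
    p = float(stats.f.sf(f_stat, df1, df2))
    return float(f_stat), float(df1), float(df2), p


@dataclass(frozen=True)
class PairwiseResult:
    """One post-hoc pairwise comparison (mean difference a - b)."""

    group_a: str
    group_b: str
    estimate: float
    statistic: float
    df: float
    p: float


def games_howell(
    groups: Sequence[np.ndarray], labels: Sequence[str] | None = None
) -> list[PairwiseResult]:
    """Games-Howell post-hoc pairwise comparisons.

    Standard errors come from unpooled per-group variances, each pair gets
    Welch-Satterthwaite degrees of freedom, and p-values come from the
    studentized-range distribution with ``k`` (the number of groups) as
    the range parameter and ``q = |mean_a - mean_b| * sqrt(2) / SE``.
    """
    arrays = _check_groups(groups)
    k = len(arrays)
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    n = [g.size for g in arrays]
    m = [g.mean() for g in arrays]
    v = [g.var(ddof=1) for g in arrays]
    results = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = m[i] - m[j]
            se_sq = v[i] / n[i] + v[j] / n[j]
            se = math.sqrt(se_sq)
            if se == 0.0:
                q = 0.0 if diff == 0 else math.inf
                p = 1.0 if diff == 0 else 0.0
                df = float(n[i] + n[j] - 2)
            else:
                df = se_sq**2 / (
                    (v[i] / n[i]) ** 2 / (n[i] - 1)
                    + (v[j] / n[j]) ** 2 / (n[j] - 1)
                )
                q = abs(diff) * math.sqrt(2.0) / se
                p = float(np.clip(stats.studentized_range.sf(q, k, df), 0.0, 1.0))
            results.append(
                PairwiseResult(labels[i], labels[j], float(diff), float(q), float(df), p)
            )
    return results


def anova_tukey(
    groups: Sequence[np.ndarray], labels: Sequence[str] | None = None
) -> tuple[float, float, list[PairwiseResult]]:
    """Classical one-way ANOVA followed by Tukey's HSD."""
    arrays = _check_groups(groups)
    k = len(arrays)
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    f_stat, p = stats.f_oneway(*arrays)
    hsd = stats.tukey_hsd(*arrays)
    n_total = sum(g.size for g in arrays)
    df_err = n_total - k
    mse = sum((g.size - 1) * g.var(ddof=1) for g in arrays) / df_err
    results = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(hsd.statistic[i, j])
            se = math.sqrt(mse / 2.0 * (1.0 / arrays[i].size + 1.0 / arrays[j].size))
            q = abs(diff) / se if se > 0 else 0.0
            results.append(
                PairwiseResult(
                    labels[i],
                    labels[j],
                    diff,
                    float(q),
                    float(df_err),
                    float(hsd.pvalue[i, j]),
                )
            )
    return float(f_stat), float(p), results


# ---------------------------------------------------------------------------
# Decision procedure
# ---------------------------------------------------------------------------


@dataclass
class AnalysisReport:
    """Full record of one group comparison."""

    method: str  # "anova_tukey" or "welch_games_howell"
    bartlett_statistic: float
    bartlett_p: float
    equal_sizes: bool
    omnibus_statistic: float
    omnibus_df1: float
    omnibus_df2: float
    omnibus_p: float
    pairwise: list[PairwiseResult]
    control: str | None = None
    alpha: float = 0.05
    warnings: list[str] = field(default_factory=list)

    def significant_pairs(self) -> list[PairwiseResult]:
        return [r for r in self.pairwise if r.p < self.alpha]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.pairwise])


def select_and_run(
    groups: Mapping[str, np.ndarray],
    control: str,
    alpha: float = 0.05,
    comparisons: str = "vs_control",
) -> AnalysisReport:
    """Run the full comparison procedure on labelled groups.

    Bartlett's test decides the branch: homoscedastic *and* exactly
    equal-sized groups go to classical ANOVA + Tukey HSD, anything else
    to Welch's ANOVA + Games-Howell.  ``comparisons`` is ``"vs_control"``
    (default, only pairs involving the control are reported) or
    ``"all_pairs"``.
    """
    if control not in groups:
        raise ValueError(
            f"control group {control!r} not among groups {sorted(groups)}"
        )
    if comparisons not in ("vs_control", "all_pairs"):
        raise ValueError(f"unknown comparisons mode {comparisons!r}")
    labels = list(groups)
    arrays = _check_groups([groups[lab] for lab in labels])
    notes: list[str] = []

    b_stat, b_p = bartlett_test(arrays)
    equal_sizes = len({g.size for g in arrays}) == 1
    if b_p >= alpha and equal_sizes:
        method = "anova_tukey"
        f_stat, p, pairwise = anova_tukey(arrays, labels)
        df1 = float(len(arrays) - 1)
        df2 = float(sum(g.size for g in arrays) - len(arrays))
    else:
        method = "welch_games_howell"
        try:
            f_stat, df1, df2, p = welch_anova(arrays)
        except DegenerateVarianceError:
            notes.append(
                "zero-variance group: fell back to classical ANOVA + Tukey"
            )
            warnings.warn(notes[-1], stacklevel=2)
            method = "anova_tukey"
            f_stat, p, pairwise = anova_tukey(arrays, labels)
            df1 = float(len(arrays) - 1)
            df2 = float(sum(g.size for g in arrays) - len(arrays))
        else:
            pairwise = games_howell(arrays, labels)

    if comparisons == "vs_control":
        pairwise = [
            r for r in pairwise if control in (r.group_a, r.group_b)
        ]
    return AnalysisReport(
        method=method,
        bartlett_statistic=b_stat,
        bartlett_p=b_p,
        equal_sizes=equal_sizes,
        omnibus_statistic=f_stat,
        omnibus_df1=df1,
        omnibus_df2=df2,
        omnibus_p=p,
        pairwise=pairwise,
        control=control,
        alpha=alpha,
        warnings=notes,
    )


def assign_moi_bin(moi: np.ndarray, bin_width: float = 0.05) -> np.ndarray:
    """Nearest-bin assignment of MOI values (default bin width 0.05)."""
    # Re-round to clean decimal bin labels (0.35, not 0.35000000000000003).
    return np.round(np.round(np.asarray(moi, dtype=float) / bin_width) * bin_width, 10)


def per_moi_analysis(
    df: pd.DataFrame,
    control: str,
    value_col: str = "log2fc",
    alpha: float = 0.05,
    bin_width: float = 0.05,
    min_n: int = 2,
) -> dict[float, AnalysisReport]:
    """Independent group comparison within each MOI bin.

    No multiple-testing correction is applied across bins; each bin is
    analysed exactly as a standalone experiment.  Bins where any
    condition has fewer than ``min_n`` plates, or the control is absent,
    are skipped.
    """
    df = df.copy()
    df["moi_bin"] = assign_moi_bin(df["moi"].to_numpy(), bin_width)
    reports: dict[float, AnalysisReport] = {}
    for moi_bin, sub in df.groupby("moi_bin"):
        groups = {
            str(cond): g[value_col].to_numpy(dtype=float)
            for cond, g in sub.groupby("condition")
        }
        if control not in groups or len(groups) < 2:
            continue
        if any(len(v) < min_n for v in groups.values()):
            continue
        reports[float(moi_bin)] = select_and_run(groups, control, alpha=alpha)
    return reports


def percent_change(
    treated: np.ndarray, control: np.ndarray, mode: str = "raw"
) -> UValue:
    """Percent reduction of the treated group relative to control.

    Returns ``100 * (1 - mean_treated / mean_control)`` — positive for a
    reduction, negative for an increase — with a delta-method standard
    uncertainty from both standard errors of the mean.  ``mode="raw"``
    compares arithmetic means; ``mode="log2"`` back-transforms the mean
    log2 fold change (geometric mean ratio) first.
    """
    t = np.asarray(treated, dtype=float)
    c = np.asarray(control, dtype=float)
    if t.size < 1 or c.size < 1:
        raise ValueError("both groups must be non-empty")
    if mode == "raw":
        mt, mc = t.mean(), c.mean()
        sem_t = t.std(ddof=1) / math.sqrt(t.size) if t.size > 1 else 0.0
        sem_c = c.std(ddof=1) / math.sqrt(c.size) if c.size > 1 else 0.0
        if mc <= 0:
            raise ValueError(f"control mean must be positive, got {mc}")
        ratio = UValue(mt, sem_t) / UValue(mc, sem_c)
    elif mode == "log2":
        lt, lc = t.mean(), c.mean()
        sem_t = t.std(ddof=1) / math.sqrt(t.size) if t.size > 1 else 0.0
        sem_c = c.std(ddof=1) / math.sqrt(c.size) if c.size > 1 else 0.0
        delta = UValue(lt, sem_t) - UValue(lc, sem_c)
        ratio_val = 2.0**delta.value
        ratio = UValue(ratio_val, ratio_val * math.log(2.0) * delta.sd)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return UValue(100.0, 0.0) - ratio.scale(100.0)
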