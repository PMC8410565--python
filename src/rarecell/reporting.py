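"""Per-sample enumeration and cohort-level analytics.

Covers the statistics a clinical CTC study reports: spike-in accuracy
(recovery rate) and precision (%CV), per-group positivity, count-threshold
diagnostics with ROC analysis, nonparametric and categorical group
comparisons, and Kaplan–Meier recurrence analysis with log-rank tests.
Counts are normalized to a 5 mL blood draw.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import roc_auc_score_ties

__all__ = [
    "SampleResult",
    "DiagnosticSummary",
    "KMResult",
    "enumerate_sample",
    "recovery_rate",
    "cv_percent",
    "positivity_rate",
    "diagnostic_metrics",
    "roc_auc_counts",
    "youden_threshold",
    "compare_groups",
    "km_recurrence",
    "cohort_report",
    "combined_marker_auc",
]


@dataclass(frozen=True)
class SampleResult:
    """Per-blood-sample enumeration result."""

    sample_id: str
    cells_screened: int
    ctc_count: int
    ctm_count: int
    blood_volume_ml: float = 5.0

    def __post_init__(self) -> None:
        if self.ctc_count > self.cells_screened:
            raise ValueError("ctc_count cannot exceed cells_screened")
        if self.ctm_count > max(self.ctc_count, 0):
            raise ValueError("ctm_count cannot exceed ctc_count")

    @property
    def ctc_per_5ml(self) -> float:
        return self.ctc_count * 5.0 / self.blood_volume_ml

    @property
    def ctm_per_5ml(self) -> float:
        return self.ctm_count * 5.0 / self.blood_volume_ml


def enumerate_sample(
    calls: pd.DataFrame,
    sample_id: str = "sample",
    blood_volume_ml: float = 5.0,
    adjacency_factor: float = 1.0,
) -> SampleResult:
    """Enumerate CTCs and tumor microemboli (CTM) in one sample's calls.

    ``ctc_count`` sums nuclei over final-label CTC objects (a k-nucleated
    cluster object contributes k cells).  An object counts toward
    ``ctm_count`` when it is multi-nucleated or its centroid lies within
    an adjacency radius (``adjacency_factor`` × the mean CTC equivalent
    diameter) of another CTC object in the same field.  ``cells_screened``
    sums nuclei over all objects.
    """
    if calls.empty:
        return SampleResult(sample_id, 0, 0, 0, blood_volume_ml)
    nuclei = calls["nuclei_count"] if "nuclei_count" in calls.columns \
        else pd.Series(1, index=calls.index)
    cells_screened = int(nuclei.sum())
    is_ctc = calls["final_label"] == "CTC" if "final_label" in calls.columns \
        else pd.Series(False, index=calls.index)
    ctc = calls[is_ctc]
    ctc_count = int(nuclei[is_ctc].sum())
    ctm_count = 0
    if len(ctc):
        multi = (nuclei[is_ctc] >= 2).to_numpy()
        adjacent = np.zeros(len(ctc), dtype=bool)
        if {"centroid_x_um", "centroid_y_um"}.issubset(ctc.columns) and len(ctc) > 1:
            diam = float(ctc["equiv_diameter_um"].mean()) \
                if "equiv_diameter_um" in ctc.columns else 10.0
            radius = adjacency_factor * diam
            fields = ctc["field_id"] if "field_id" in ctc.columns \
                else pd.Series(0, index=ctc.index)
            xy = ctc[["centroid_x_um", "centroid_y_um"]].to_numpy(dtype=float)
            fid = fields.to_numpy()
            for i in range(len(ctc)):
                same = fid == fid[i]
                same[i] = False
                if same.any():
                    d = np.hypot(*(xy[same] - xy[i]).T)
                    adjacent[i] = bool((d <= radius).any())
        ctm_count = int((multi | adjacent).sum())
    return SampleResult(sample_id, cells_screened, ctc_count, ctm_count,
                        blood_volume_ml)


def recovery_rate(recovered: float, spiked: float) -> float:
    """Recovery rate (%) = recovered / spiked × 100."""
    if spiked <= 0:
        raise ValueError("recovery rate undefined for spiked <= 0")
    rate = 100.0 * recovered / spiked
    if rate > 100.0:
        warnings.warn(f"recovery rate {rate:.1f}% exceeds 100% (possible miscount)")
    return rate


def cv_percent(values: Sequence[float]) -> float:
    """Coefficient of variation (%) = 100 · sample sd / mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("%CV needs at least 2 values")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("%CV undefined for zero mean")
    return float(100.0 * arr.std(ddof=1) / mean)


def positivity_rate(
    cohort: pd.DataFrame, group: str, threshold: int = 1
) -> tuple[float, int, int]:
    """Percent of subjects in a group with count ≥ threshold.

    Returns ``(percent, n_positive, n_total)``.
    """
    sub = cohort[cohort["group"] == group]
    if sub.empty:
        raise ValueError(f"group {group!r} not present or empty")
    n_pos = int((sub["ctc_count"] >= threshold).sum())
    n = len(sub)
    return 100.0 * n_pos / n, n_pos, n


@dataclass(frozen=True)
class DiagnosticSummary:
    """Count-threshold diagnostic performance with binomial 95% CIs."""

    threshold: int
    sensitivity: float
    specificity: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None
    n_cases: int = 0
    n_controls: int = 0


def _binom_ci(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Clopper–Pearson exact binomial CI."""
    lo = stats.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)


def diagnostic_metrics(
    cases: Sequence[int], controls: Sequence[int], threshold: int = 1
) -> DiagnosticSummary:
    """Sensitivity/specificity of the count-≥-threshold rule."""
    cases = np.asarray(cases)
    controls = np.asarray(controls)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both arms must be nonempty")
    tp = int((cases >= threshold).sum())
    tn = int((controls < threshold).sum())
    sens = tp / cases.size
    spec = tn / controls.size
    return DiagnosticSummary(
        threshold=threshold,
        sensitivity=sens,
        specificity=spec,
        sensitivity_ci=_binom_ci(tp, cases.size),
        specificity_ci=_binom_ci(tn, controls.size),
        n_cases=int(cases.size),
        n_controls=int(controls.size),
    )


def _delong_ci(cases: np.ndarray, controls: np.ndarray,
               auc: float, alpha: float = 0.05) -> tuple[float, float]:
    """DeLong CI from placement values (valid for ties via midranks)."""
    m, n = len(cases), len(controls)
    all_vals = np.concatenate([cases, controls])
    ranks = stats.rankdata(all_vals)
    rank_cases = stats.rankdata(cases)
    rank_controls = stats.rankdata(controls)
    v10 = (ranks[:m] - rank_cases) / n          # placements of cases
    v01 = 1.0 - (ranks[m:] - rank_controls) / m  # placements of controls
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / n)
    z = stats.norm.ppf(1 - alpha / 2)
    return float(max(0.0, auc - z * se)), float(min(1.0, auc + z * se))


def roc_auc_counts(
    cases: Sequence[float],
    controls: Sequence[float],
    ci: str | None = "delong",
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, tuple[float, float] | None]:
    """ROC AUC over all count thresholds (Mann–Whitney, ties ½).

    ``ci`` selects the interval method: ``"delong"`` (default,
    deterministic), ``"bootstrap"``, or ``None``.
    """
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both arms must be nonempty")
    scores = np.concatenate([cases, controls])
    truth = np.concatenate([np.ones(cases.size, bool), np.zeros(controls.size, bool)])
    auc = roc_auc_score_ties(scores, truth)
    if ci is None:
        return auc, None
    if ci == "delong":
        return auc, _delong_ci(cases, controls, auc)
    if ci == "bootstrap":
        rng = np.random.default_rng(seed)
        vals = np.empty(n_boot)
        for b in range(n_boot):
            c = rng.choice(cases, cases.size, replace=True)
            d = rng.choice(controls, controls.size, replace=True)
            s = np.concatenate([c, d])
            vals[b] = roc_auc_score_ties(s, truth)
        lo, hi = np.percentile(vals, [2.5, 97.5])
        return auc, (float(lo), float(hi))
    raise ValueError(f"unknown CI method {ci!r}")


def youden_threshold(cases: Sequence[int], controls: Sequence[int]) -> int:
    """Integer count threshold maximizing Youden's J = sens + spec − 1."""
    cases = np.asarray(cases)
    controls = np.asarray(controls)
    candidates = np.unique(np.concatenate([cases, controls]))
    candidates = np.unique(np.concatenate([candidates, candidates + 1]))
    best_t, best_j = int(candidates[0]), -np.inf
    for t in candidates:
        j = (cases >= t).mean() + (controls < t).mean() - 1.0
        if j > best_j:
            best_j, best_t = j, int(t)
    return best_t


def compare_groups(
    x,
    y=None,
    test: str = "mann-whitney",
    continuity: bool = True,
) -> tuple[float, float]:
    """Two-sided between-group test; returns (statistic, p).

    ``mann-whitney``, ``wilcoxon-paired`` and ``t`` take two sample
    vectors; ``chi2`` and ``fisher`` take a 2×2 contingency table as ``x``
    (``continuity`` toggles the Yates correction for ``chi2``).  Exact
    small-sample nulls are used where the underlying routine supports
    them (Mann–Whitney at n ≤ 10 per arm without heavy ties; Fisher is
    always exact).  Identical paired vectors give p = 1 (all-ties policy).
    """
    if test == "mann-whitney":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        method = "exact" if max(x.size, y.size) <= 10 else "auto"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)
    if test == "wilcoxon-paired":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size != y.size:
            raise ValueError("paired test needs equal-length vectors")
        d = x - y
        if not np.any(d):
            return 0.0, 1.0  # all ties: no evidence of a shift
        res = stats.wilcoxon(x, y, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    if test == "t":
        res = stats.ttest_ind(np.asarray(x, float), np.asarray(y, float))
        return float(res.statistic), float(res.pvalue)
    if test == "chi2":
        res = stats.chi2_contingency(np.asarray(x), correction=continuity)
        return float(res.statistic), float(res.pvalue)
    if test == "fisher":
        stat, p = stats.fisher_exact(np.asarray(x))
        return float(stat), float(p)
    raise ValueError(f"unknown test {test!r}")


@dataclass
class KMResult:
    """Kaplan–Meier recurrence analysis result."""

    curves: dict[str, pd.DataFrame]       # group -> (time, survival)
    medians: dict[str, float | None]      # None = not reached
    logrank_statistic: float | None
    logrank_p: float | None
    n_per_group: dict[str, int] = field(default_factory=dict)


def km_recurrence(
    cohort: pd.DataFrame,
    group_col: str | None = None,
    time_col: str = "ttr_months",
    event_col: str = "recurrence",
) -> KMResult:
    """Kaplan–Meier curves by group with a log-rank comparison.

    With ``group_col=None``, subjects are grouped by CTC status
    (``ctc_count`` ≥ 1 vs 0).  The reported median is the first time the
    survival curve reaches 0.5 or below; ``None`` means not reached.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    data = cohort.dropna(subset=[time_col, event_col]).copy()
    if data.empty:
        raise ValueError("no subjects with outcome data")
    if (data[time_col] <= 0).any():
        raise ValueError("times must be positive")
    if not data[event_col].isin([0, 1]).all():
        raise ValueError("events must be 0/1")
    if group_col is None:
        data["_grp"] = np.where(data["ctc_count"] >= 1, "CTC>=1", "CTC=0")
        group_col = "_grp"

    curves: dict[str, pd.DataFrame] = {}
    medians: dict[str, float | None] = {}
    n_per_group: dict[str, int] = {}
    for grp, sub in data.groupby(group_col, sort=True):
        if sub.empty:
            raise ValueError(f"group {grp!r} has zero subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(sub[time_col], event_observed=sub[event_col])
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        curves[str(grp)] = sf
        med = kmf.median_survival_time_
        medians[str(grp)] = None if np.isinf(med) else float(med)
        n_per_group[str(grp)] = len(sub)

    logrank_stat = logrank_p = None
    if data[group_col].nunique() > 1:
        res = multivariate_logrank_test(
            data[time_col], data[group_col], data[event_col]
        )
        logrank_stat = float(res.test_statistic)
        logrank_p = float(res.p_value)
    return KMResult(curves, medians, logrank_stat, logrank_p, n_per_group)


def combined_marker_auc(
    cohort: pd.DataFrame,
    case_groups: Sequence[str],
    control_groups: Sequence[str],
    afp_col: str = "afp_ng_ml",
) -> float:
    """In-sample AUC of a logistic combination of CTC count and log-AFP.

    A reconstruction of a count-plus-serology composite score; the fitted
    coefficients depend on the cohort at hand and are not a validated
    clinical model.
    """
    from sklearn.linear_model import LogisticRegression

    sub = cohort[cohort["group"].isin(list(case_groups) + list(control_groups))]
    sub = sub.dropna(subset=[afp_col])
    y = sub["group"].isin(case_groups).to_numpy(int)
    X = np.column_stack([
        sub["ctc_count"].to_numpy(float),
        np.log10(sub[afp_col].to_numpy(float) + 1.0),
    ])
    model = LogisticRegression(max_iter=1000).fit(X, y)
    scores = model.predict_proba(X)[:, 1]
    return roc_auc_score_ties(scores, y.astype(bool))


def cohort_report(
    cohort: pd.DataFrame,
    config: dict | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Structured per-cohort report: group summaries, positivity,
    diagnostics against the control group, and (when outcome columns are
    present) a recurrence section.  Optionally writes JSON + TSV + plots.
    """
    config = config or {}
    control_group = config.get("control_group", "HD")
    threshold = int(config.get("positivity_threshold", 1))
    groups = list(cohort["group"].unique())

    summaries = {}
    for grp in groups:
        counts = cohort.loc[cohort["group"] == grp, "ctc_count"]
        pct, n_pos, n = positivity_rate(cohort, grp, threshold)
        summaries[grp] = {
            "n": n,
            "mean": float(counts.mean()),
            "sd": float(counts.std(ddof=1)) if n > 1 else 0.0,
            "median": float(counts.median()),
            "positivity_percent": pct,
            "n_positive": n_pos,
        }

    report: dict = {"group_summaries": summaries,
                    "positivity_threshold": threshold}

    if control_group in groups:
        controls = cohort.loc[cohort["group"] == control_group, "ctc_count"]
        case_groups = [g for g in groups if g != control_group]
        cases = cohort.loc[cohort["group"].isin(case_groups), "ctc_count"]
        if len(cases):
            summary = diagnostic_metrics(cases, controls, threshold)
            auc, auc_ci = roc_auc_counts(cases, controls)
            report["diagnostics"] = {
                "control_group": control_group,
                "threshold": threshold,
                "sensitivity_percent": 100.0 * summary.sensitivity,
                "specificity_percent": 100.0 * summary.specificity,
                "auc": auc,
                "auc_ci": list(auc_ci) if auc_ci else None,
                "youden_threshold": youden_threshold(cases, controls),
            }

    has_outcomes = (
        {"recurrence", "ttr_months"}.issubset(cohort.columns)
        and cohort["ttr_months"].notna().any()
    )
    if has_outcomes:
        with_outcome = cohort.dropna(subset=["recurrence", "ttr_months"])
        km = km_recurrence(with_outcome)
        report["recurrence"] = {
            "medians_months": km.medians,
            "logrank_statistic": km.logrank_statistic,
            "logrank_p": km.logrank_p,
            "n_per_group": km.n_per_group,
        }
        pos = with_outcome[with_outcome["ctc_count"] >= threshold]
        if len(pos):
            report["recurrence"]["positivity_conditional_recurrence_percent"] = (
                100.0 * float(pos["recurrence"].mean())
            )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(json.dumps(report, indent=2))
        pd.DataFrame(summaries).T.to_csv(out_dir / "group_summaries.tsv", sep="\t")
        _write_report_plots(cohort, report, out_dir, control_group)
    return report


def _write_report_plots(cohort: pd.DataFrame, report: dict, out_dir: Path,
                        control_group: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    groups = list(cohort["group"].unique())
    data = [cohort.loc[cohort["group"] == g, "ctc_count"] for g in groups]
    ax.boxplot(data, tick_labels=groups)
    ax.set_ylabel("CTC count / 5 mL")
    fig.tight_layout()
    fig.savefig(out_dir / "counts_by_group.png", dpi=120)
    plt.close(fig)

    if "recurrence" in report:
        with_outcome = cohort.dropna(subset=["recurrence", "ttr_months"])
        km = km_recurrence(with_outcome)
        fig, ax = plt.subplots(figsize=(6, 4))
        for grp, sf in km.curves.items():
            ax.step(sf["time"], 1.0 - sf["survival"], where="post", label=grp)
        ax.set_xlabel("months")
        ax.set_ylabel("cumulative recurrence")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out_dir / "recurrence_km.png", dpi=120)
        plt.close(fig)
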