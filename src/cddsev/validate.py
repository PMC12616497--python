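"""External-validation statistics for the global severity score.

Pearson correlations (with Fisher-z confidence intervals) against EEG power
ratios, quality of life and behavior; a two-sample age-group comparison;
and test-retest reliability via the intraclass correlation computed from
the two-way ANOVA decomposition, with interpretation bands (poor < 0.5,
moderate 0.5-0.75, good 0.75-0.9, excellent > 0.9).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import EXTERNAL_VARS, OBSERVED_VARS
from .scoring import WeightSet, apply_weights, harmonize

log = logging.getLogger(__name__)


@dataclass
class CorrelationResult:
    r: float
    n: int
    ci95: tuple[float, float]

    def to_dict(self) -> dict:
        return {"r": self.r, "n": self.n, "ci95": list(self.ci95)}


@dataclass
class ReliabilityResult:
    icc: float
    ci95: tuple[float, float]
    n_subjects: int
    band: str
    form: str = "ICC(A,1) two-way mixed, absolute agreement, single measurement"

    def to_dict(self) -> dict:
        return {"icc": self.icc, "ci95": list(self.ci95),
                "n_subjects": self.n_subjects, "band": self.band,
                "form": self.form}


def _band(icc: float) -> str:
    if icc > 0.9:
        return "excellent"
    if icc >= 0.75:
        return "good"
    if icc >= 0.5:
        return "moderate"
    return "poor"


def pearson(x, y) -> CorrelationResult:
    """Pearson correlation over pairwise-complete observations with a
    Fisher-z 95% confidence interval.  Dropped incomplete pairs are counted
    via the returned n."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    n = int(ok.sum())
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs (got {n})")
    xv, yv = x[ok], y[ok]
    if xv.std() == 0 or yv.std() == 0:
        raise ValueError("zero variance in one of the vectors")
    r = float(stats.pearsonr(xv, yv).statistic)
    if n > 3 and abs(r) < 1.0:
        z = np.arctanh(r)
        half = stats.norm.ppf(0.975) / np.sqrt(n - 3)
        ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    else:
        ci = (r, r)
    return CorrelationResult(r=r, n=n, ci95=ci)


def _anova_mean_squares(table: np.ndarray) -> tuple[float, float, float]:
    """(MS_rows, MS_cols, MS_error) of a complete n x k two-way layout."""
    n, k = table.shape
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((table - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    return (ss_rows / (n - 1), ss_cols / (k - 1),
            ss_err / ((n - 1) * (k - 1)))


def icc_test_retest(pairs, *, form: str = "icc2", alpha: float = 0.05
                    ) -> ReliabilityResult:
    """Test-retest ICC from the two-way ANOVA decomposition.

    ``pairs``: n x 2 array or DataFrame with columns ('test', 'retest');
    subjects missing either occasion are excluded (logged).  Default form
    is the two-way mixed-effects, absolute-agreement, single-measurement
    coefficient; ``form='icc1'`` gives the one-way random alternative.
    The 95% CI uses the F-distribution method.
    """
    if isinstance(pairs, pd.DataFrame):
        cols = [c for c in ("test", "retest") if c in pairs.columns]
        table = pairs[cols].to_numpy(dtype=float) if len(cols) == 2 \
            else pairs.to_numpy(dtype=float)
    else:
        table = np.asarray(pairs, dtype=float)
    if table.ndim != 2 or table.shape[1] != 2:
        raise ValueError("pairs must be an n x 2 table")
    ok = ~np.isnan(table).any(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.info("excluded %d subjects missing an occasion", n_dropped)
    table = table[ok]
    n, k = table.shape
    if n < 2:
        raise ValueError("need at least 2 subjects with both occasions")

    msr, msc, mse = _anova_mean_squares(table)
    if form == "icc1":
        # one-way random: occasions not modeled as a systematic effect
        ss_within = np.sum((table - table.mean(axis=1, keepdims=True)) ** 2)
        msw = ss_within / (n * (k - 1))
        denom = msr + (k - 1) * msw
        icc = (msr - msw) / denom if denom > 0 else 1.0
        fl = (msr / msw) if msw > 0 else np.inf
        f1 = stats.f.ppf(1 - alpha / 2, n - 1, n * (k - 1))
        f2 = stats.f.ppf(1 - alpha / 2, n * (k - 1), n - 1)
        lo = (fl / f1 - 1) / (fl / f1 + k - 1) if np.isfinite(fl) else 1.0
        hi = (fl * f2 - 1) / (fl * f2 + k - 1) if np.isfinite(fl) else 1.0
        form_label = "ICC(1,1) one-way random, single measurement"
    elif form == "icc2":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        if denom <= 0 and mse == 0 and msc == 0:
            icc = 1.0
        else:
            icc = (msr - mse) / denom
        if mse == 0 and msc == 0:
            lo = hi = 1.0
        else:
            a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
            b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
            if np.isfinite(a) and (a * msc) ** 2 + (b * mse) ** 2 > 0:
                v = (a * msc + b * mse) ** 2 / (
                    (a * msc) ** 2 / (k - 1)
                    + (b * mse) ** 2 / ((n - 1) * (k - 1)))
                f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
                f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
                lo = n * (msr - f1 * mse) / (
                    f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
                hi = n * (f2 * msr - mse) / (
                    k * msc + (k * n - k - n) * mse + n * f2 * msr)
            else:
                lo = hi = icc
        form_label = "ICC(A,1) two-way mixed, absolute agreement, single measurement"
    else:
        raise ValueError(f"unknown ICC form {form!r}")

    icc = float(icc)
    return ReliabilityResult(icc=icc, ci95=(float(lo), float(hi)),
                             n_subjects=n, band=_band(icc), form=form_label)


def age_group_t_test(scores, groups, *, flavor: str = "welch") -> dict:
    """Two-sample t-test of severity scores between age groups.

    Welch (unequal variances) by default; ``flavor='pooled'`` for the
    classical equal-variance test.  Returns t, two-sided p, per-group n.
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    ok = ~np.isnan(scores)
    scores, groups = scores[ok], groups[ok]
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(labels)}")
    a = scores[groups == labels[0]]
    b = scores[groups == labels[1]]
    if min(len(a), len(b)) < 2:
        raise ValueError("each group needs at least 2 members")
    res = stats.ttest_ind(a, b, equal_var=(flavor == "pooled"))
    return {"t": float(res.statistic), "p": float(res.pvalue),
            "flavor": flavor,
            "groups": {str(labels[0]): len(a), str(labels[1]): len(b)}}


def validation_report(cohort: pd.DataFrame, scores, *,
                      outdir: str | Path | None = None,
                      ttest_flavor: str = "welch") -> dict:
    """Correlate global severity with every available external correlate,
    compare age groups, and (optionally) write histogram/scatter figures.

    ``scores``: per-row standardized global severity aligned with the
    baseline rows of ``cohort``.  Correlates with no observations are
    omitted with a note.
    """
    base = cohort[cohort.get("visit", "baseline") == "baseline"].reset_index(drop=True)
    s = np.asarray(scores, dtype=float)
    if len(s) != len(base):
        raise ValueError("scores are not aligned with the baseline rows")
    report: dict = {"correlations": {}, "omitted": []}
    for var in EXTERNAL_VARS:
        if var not in base.columns or base[var].notna().sum() == 0:
            report["omitted"].append(var)
            continue
        try:
            report["correlations"][var] = pearson(s, base[var]).to_dict()
        except ValueError as exc:
            report["omitted"].append(var)
            log.warning("correlate %s skipped: %s", var, exc)
    if "age_group" in base.columns and base["age_group"].nunique() == 2:
        report["age_group_t_test"] = age_group_t_test(
            s, base["age_group"], flavor=ttest_flavor)

    if outdir is not None:
        report["figures"] = _write_figures(base, s, Path(outdir))
    return report


def _write_figures(base: pd.DataFrame, s: np.ndarray, outdir: Path) -> list[str]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharex=True)
    panels = [("all", np.ones(len(base), dtype=bool))]
    if "age_group" in base.columns:
        panels += [(g, (base["age_group"] == g).to_numpy())
                   for g in ("under7", "over7")]
    for ax, (label, mask) in zip(axes, panels):
        vals = s[mask & ~np.isnan(s)]
        ax.hist(vals, bins=15, color="steelblue", edgecolor="white")
        ax.set_title(f"{label} (n={len(vals)})")
        ax.set_xlabel("global severity (z)")
    axes[0].set_ylabel("count")
    fig.tight_layout()
    p = outdir / "severity_histograms.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(str(p))

    for var in EXTERNAL_VARS:
        if var not in base.columns:
            continue
        y = base[var].to_numpy(dtype=float)
        ok = ~np.isnan(s) & ~np.isnan(y)
        if ok.sum() < 3:
            continue
        fig, ax = plt.subplots(figsize=(4.2, 3.6))
        ax.scatter(s[ok], y[ok], s=14, alpha=0.6)
        slope, intercept = np.polyfit(s[ok], y[ok], 1)
        xs = np.linspace(s[ok].min(), s[ok].max(), 50)
        ax.plot(xs, intercept + slope * xs, color="black")
        ax.set_xlabel("global severity (z)")
        ax.set_ylabel(var)
        fig.tight_layout()
        p = outdir / f"scatter_{var}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(str(p))
    return written


def reliability_table(cohort: pd.DataFrame, weights: WeightSet, *,
                      form: str = "icc2") -> pd.DataFrame:
    """Component and global-score test-retest ICCs from a cohort with
    baseline and retest visits (weighted-average global score, complete
    components only)."""
    harm = harmonize(cohort)
    base = harm[harm["visit"] == "baseline"].set_index("subject_id")
    retest = harm[harm["visit"] == "retest"].set_index("subject_id")
    common = base.index.intersection(retest.index)
    if len(common) < 2:
        raise ValueError("need at least 2 subjects with both visits")
    rows = []
    for var in OBSERVED_VARS:
        pairs = np.column_stack([base.loc[common, var], retest.loc[common, var]])
        try:
            res = icc_test_retest(pairs, form=form)
        except ValueError:
            continue
        rows.append({"component": var, **res.to_dict()})

    complete = (~base.loc[common, list(OBSERVED_VARS)].isna().any(axis=1)) & \
               (~retest.loc[common, list(OBSERVED_VARS)].isna().any(axis=1))
    ids = common[complete]
    if len(ids) >= 2:
        g1 = apply_weights(base.loc[ids], weights)
        g2 = apply_weights(retest.loc[ids], weights)
        res = icc_test_retest(np.column_stack([g1, g2]), form=form)
        rows.append({"component": "global_severity", **res.to_dict()})
    out = pd.DataFrame(rows)
    out[["ci_low", "ci_high"]] = pd.DataFrame(out["ci95"].tolist(), index=out.index)
    return out.drop(columns="ci95")


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=float) + "\n")
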