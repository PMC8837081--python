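"""Refractive prediction-error statistics for method comparison.

For each eye, the prediction error is the actual postoperative manifest
spherical equivalent minus the refraction the formula predicted (D;
negative means the eye ended more myopic than predicted).  A cohort is
summarised by the mean numerical error (bias), the mean and median absolute
error, and the percentages of eyes within +/-0.25, +/-0.50 and +/-1.00 D of
target.  Bias is tested against zero with a one-sample t-test; two methods
are compared on absolute error with the Wilcoxon signed-rank test (paired
by eye) and on band percentages with Fisher's exact test, with Bonferroni
correction across comparator methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "PredictionRecord",
    "OutcomeSummary",
    "summarize",
    "test_bias",
    "compare_absolute",
    "compare_bands",
    "bonferroni",
    "BANDS_D",
    "method_comparison_table",
]

#: Error bands (D) reported in refractive-outcome studies.
BANDS_D = (0.25, 0.50, 1.00)

#: Largest post-zero-drop sample for which the Wilcoxon null is enumerated
#: exactly; above this a normal approximation with continuity correction is
#: used, matching common statistical-package behaviour.
WILCOXON_EXACT_MAX_N = 25


@dataclass(frozen=True)
class PredictionRecord:
    """Per-eye prediction outcome for one method."""

    eye_id: str
    method: str
    predicted_d: float
    actual_d: float

    @property
    def error_d(self) -> float:
        return self.actual_d - self.predicted_d


@dataclass(frozen=True)
class OutcomeSummary:
    """Cohort-level prediction-error statistics for one method."""

    method: str
    n: int
    mean_numerical_d: float
    sd_numerical_d: float
    mean_absolute_d: float
    sd_absolute_d: float
    median_absolute_d: float
    pct_within_025: float
    pct_within_050: float
    pct_within_100: float
    t_p: float | None = None

    def band_pct(self, threshold_d: float) -> float:
        lut = {0.25: self.pct_within_025, 0.50: self.pct_within_050,
               1.00: self.pct_within_100}
        return lut[threshold_d]

    def summary(self) -> str:
        t_p = "n/a" if self.t_p is None else f"{self.t_p:.3f}"
        return "\n".join([
            f"Prediction error, {self.method} (n = {self.n})",
            "-" * 46,
            f"numerical  {self.mean_numerical_d:+.2f} +/- {self.sd_numerical_d:.2f} D"
            f"   (t-test vs 0: p = {t_p})",
            f"absolute    {self.mean_absolute_d:.2f} +/- {self.sd_absolute_d:.2f} D"
            f"   median {self.median_absolute_d:.2f} D",
            f"within +/-0.25 D  {self.pct_within_025:5.1f}%",
            f"within +/-0.50 D  {self.pct_within_050:5.1f}%",
            f"within +/-1.00 D  {self.pct_within_100:5.1f}%",
        ])


def _as_errors(errors) -> np.ndarray:
    if len(errors) and isinstance(errors[0], PredictionRecord):
        errors = [r.error_d for r in errors]
    return np.asarray(errors, dtype=float)


def summarize(errors, method: str = "ISS", with_t_test: bool = True) -> OutcomeSummary:
    """Summarise per-eye prediction errors (D) for one method.

    Band membership is inclusive (|error| <= threshold); dispersions use the
    sample (n-1) standard deviation.
    """
    e = _as_errors(errors)
    if e.size == 0:
        raise ValueError("no prediction errors supplied")
    ae = np.abs(e)
    within = {b: float(np.mean(ae <= b) * 100.0) for b in BANDS_D}
    t_p = None
    if with_t_test and e.size >= 2 and np.ptp(e) > 0:
        t_p = test_bias(e)
    return OutcomeSummary(
        method=method,
        n=int(e.size),
        mean_numerical_d=float(np.mean(e)),
        sd_numerical_d=float(np.std(e, ddof=1)) if e.size > 1 else 0.0,
        mean_absolute_d=float(np.mean(ae)),
        sd_absolute_d=float(np.std(ae, ddof=1)) if e.size > 1 else 0.0,
        median_absolute_d=float(np.median(ae)),
        pct_within_025=within[0.25],
        pct_within_050=within[0.50],
        pct_within_100=within[1.00],
        t_p=t_p,
    )


def test_bias(errors) -> float:
    """Two-sided one-sample t-test of the mean numerical error against zero."""
    e = _as_errors(errors)
    if e.size < 2:
        raise ValueError("t-test needs at least 2 observations")
    if np.ptp(e) == 0:
        raise ValueError("zero variance: t-test undefined")
    return float(scipy.stats.ttest_1samp(e, 0.0).pvalue)


def compare_absolute(errors_a, errors_b) -> float:
    """Two-sided Wilcoxon signed-rank p comparing |error| of two methods,
    paired by eye.

    Zero differences are dropped; the exact null is used for up to 25
    non-zero pairs, a normal approximation with continuity correction above.
    All-zero differences are degenerate and return p = 1 with a warning.
    """
    a = np.abs(_as_errors(errors_a))
    b = np.abs(_as_errors(errors_b))
    if a.shape != b.shape:
        raise ValueError("paired comparison requires equal-length error vectors")
    d = a - b
    d = d[d != 0.0]
    if d.size == 0:
        warnings.warn(
            "all paired absolute errors identical; Wilcoxon degenerate, p = 1",
            RuntimeWarning,
            stacklevel=2,
        )
        return 1.0
    method = "exact" if d.size <= WILCOXON_EXACT_MAX_N else "approx"
    res = scipy.stats.wilcoxon(
        d, zero_method="wilcox", correction=(method == "approx"), method=method
    )
    return float(res.pvalue)


def compare_bands(count_a_in: int, n_a: int, count_b_in: int, n_b: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table of within-band counts."""
    for cnt, n in ((count_a_in, n_a), (count_b_in, n_b)):
        if n <= 0:
            raise ValueError("group size must be positive")
        if not 0 <= cnt <= n:
            raise ValueError(f"count {cnt} outside [0, {n}]")
    table = [[count_a_in, n_a - count_a_in], [count_b_in, n_b - count_b_in]]
    return float(scipy.stats.fisher_exact(table, alternative="two-sided").pvalue)


def bonferroni(p_values: Sequence[float], m: int) -> list[float]:
    """Bonferroni adjustment: each p multiplied by the number of comparisons
    m, capped at 1.  m is explicit, never inferred from len(p_values)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return [min(1.0, p * m) for p in p_values]


def method_comparison_table(
    errors_by_method: Mapping[str, Sequence[float]],
    reference: str = "ISS",
    bonferroni_m: int | None = None,
) -> pd.DataFrame:
    """Outcome table across methods: per-method summary statistics plus,
    for each non-reference method, Wilcoxon (absolute error vs reference)
    and Fisher (band percentages vs reference) p-values, raw and
    Bonferroni-adjusted.

    ``bonferroni_m`` defaults to the number of comparator (non-reference)
    methods.
    """
    if reference not in errors_by_method:
        raise ValueError(f"reference method {reference!r} not in input")
    comparators = [m for m in errors_by_method if m != reference]
    m_adj = bonferroni_m if bonferroni_m is not None else max(1, len(comparators))
    ref_err = _as_errors(errors_by_method[reference])
    ref_abs = np.abs(ref_err)

    rows = []
    for name, errs in errors_by_method.items():
        s = summarize(errs, method=name)
        row = {
            "method": name,
            "n": s.n,
            "mean_numerical_d": s.mean_numerical_d,
            "sd_numerical_d": s.sd_numerical_d,
            "t_p_vs_zero": s.t_p,
            "mean_absolute_d": s.mean_absolute_d,
            "sd_absolute_d": s.sd_absolute_d,
            "median_absolute_d": s.median_absolute_d,
            "pct_within_025": s.pct_within_025,
            "pct_within_050": s.pct_within_050,
            "pct_within_100": s.pct_within_100,
        }
        if name == reference:
            row.update(
                wilcoxon_p_vs_ref=np.nan, wilcoxon_p_adj=np.nan,
                **{f"fisher_p_{b}": np.nan for b in ("025", "050", "100")},
                **{f"fisher_p_adj_{b}": np.nan for b in ("025", "050", "100")},
            )
        else:
            e = _as_errors(errs)
            wp = compare_absolute(e, ref_err)
            row["wilcoxon_p_vs_ref"] = wp
            row["wilcoxon_p_adj"] = bonferroni([wp], m_adj)[0]
            ae = np.abs(e)
            for b, tag in zip(BANDS_D, ("025", "050", "100")):
                fp = compare_bands(
                    int(np.sum(ae <= b)), e.size, int(np.sum(ref_abs <= b)),
                    ref_err.size,
                )
                row[f"fisher_p_{tag}"] = fp
                row[f"fisher_p_adj_{tag}"] = bonferroni([fp], m_adj)[0]
        rows.append(row)
    df = pd.DataFrame(rows).set_index("method")
    # reference first, comparators in input order
    return df.loc[[reference] + comparators]
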