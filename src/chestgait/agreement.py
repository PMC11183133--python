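"""Method-comparison statistics for device validation.

Implements the agreement framework used to validate one wearing location
against a reference: Bland-Altman bias and 95% limits of agreement with
confidence intervals, mean absolute difference and mean percent error,
single-measure two-way random-effects absolute-agreement intraclass
correlation ICC(2,1) with an F-based 95% confidence interval, agreement
benchmark labels, Pearson correlation, and two-visit test-retest
reliability.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .types import AgreementResult

__all__ = [
    "bland_altman",
    "error_metrics",
    "icc_2way_random_absolute",
    "classify_agreement",
    "pearson",
    "test_retest",
    "compare_devices",
]


def _paired(test, ref) -> tuple[np.ndarray, np.ndarray]:
    test = np.asarray(test, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if test.shape != ref.shape:
        raise ValueError("test and reference must be paired (equal length)")
    ok = ~(np.isnan(test) | np.isnan(ref))
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} incomplete pair(s) dropped")
    return test[ok], ref[ok]


def bland_altman(test, ref, alpha: float = 0.05) -> dict:
    """Bland-Altman bias and 95% limits of agreement with CIs.

    bias = mean(test - ref); LoA = bias +/- 1.96 * SD(test - ref).
    The bias CI uses the t distribution (se = SD/sqrt(n)); the LoA CIs use
    the standard Bland-Altman variance ``SD^2 * (1/n + 1.96^2 / (2(n-1)))``.
    """
    test, ref = _paired(test, ref)
    n = test.size
    if n < 3:
        raise ValueError("Bland-Altman needs at least 3 pairs")
    d = test - ref
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_lo, loa_hi = bias - 1.96 * sd, bias + 1.96 * sd
    tcrit = stats.t.ppf(1 - alpha / 2, n - 1)
    se_bias = sd / np.sqrt(n)
    se_loa = sd * np.sqrt(1.0 / n + 1.96 ** 2 / (2 * (n - 1)))
    return {
        "n": n,
        "bias": bias,
        "sd": sd,
        "loa_lower": loa_lo,
        "loa_upper": loa_hi,
        "bias_ci": (bias - tcrit * se_bias, bias + tcrit * se_bias),
        "loa_lower_ci": (loa_lo - tcrit * se_loa, loa_lo + tcrit * se_loa),
        "loa_upper_ci": (loa_hi - tcrit * se_loa, loa_hi + tcrit * se_loa),
    }


def error_metrics(test, ref) -> dict:
    """Bias, mean absolute difference, and mean percent error (vs reference).

    Pairs whose reference value is zero are excluded from the percent error
    with a warning (the ratio is undefined there).
    """
    test, ref = _paired(test, ref)
    if test.size < 1:
        raise ValueError("error metrics need at least one pair")
    d = test - ref
    nonzero = ref != 0
    if not nonzero.all():
        warnings.warn(f"{int((~nonzero).sum())} pair(s) with zero reference "
                      "excluded from percent error")
    mpe = (100.0 * float(np.mean(d[nonzero] / ref[nonzero]))
           if nonzero.any() else np.nan)
    return {"bias": float(d.mean()), "mad": float(np.abs(d).mean()), "mpe": mpe}


def icc_2way_random_absolute(matrix, alpha: float = 0.05,
                             ) -> tuple[float, float, float]:
    """Single-measure ICC(2,1): two-way random effects, absolute agreement.

    ``matrix`` is subjects x raters (complete).  From the two-way ANOVA mean
    squares (rows MSR, columns MSC, error MSE):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    The 95% bounds use the F-based interval with Satterthwaite degrees of
    freedom for the lower-bound denominator.  May be negative.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("need a subjects x raters matrix, >= 3 x 2")
    if np.isnan(x).any():
        raise ValueError("ICC matrix must be complete (drop incomplete rows first)")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_tot = np.sum((x - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom if denom != 0 else 0.0
    icc = min(icc, 1.0)  # guard floating-point overshoot for identical raters

    # F-based interval (two-way random, absolute agreement, single measure)
    if mse <= 0 or abs(1 - icc) < 1e-15:
        return float(icc), float(icc), float(icc)
    a = k * icc / (n * (1 - icc))
    b = 1 + k * icc * (n - 1) / (n * (1 - icc))
    num = (a * msc + b * mse) ** 2
    den = ((a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
    v = num / den if den > 0 else (n - 1) * (k - 1)
    f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lb = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
    ub = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    return float(icc), float(lb), float(ub)


def classify_agreement(icc: float) -> str:
    """Benchmark label: <=0.4 poor, (0.4,0.6) moderate, [0.6,0.75) good,
    >=0.75 excellent."""
    if icc > 1 + 1e-9:
        raise ValueError("ICC cannot exceed 1")
    icc = min(icc, 1.0)
    if icc <= 0.4:
        return "poor"
    if icc < 0.6:
        return "moderate"
    if icc < 0.75:
        return "good"
    return "excellent"


def pearson(test, ref) -> tuple[float, float]:
    """Product-moment correlation with two-sided p from the t distribution."""
    test, ref = _paired(test, ref)
    n = test.size
    if n < 3:
        raise ValueError("Pearson correlation needs at least 3 pairs")
    if np.std(test) == 0 or np.std(ref) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(test, ref)
    return float(r), float(p)


def test_retest(visit1, visit2) -> dict:
    """Two-visit reliability: ICC(2,1) on the subjects x 2 matrix + Pearson r."""
    v1, v2 = _paired(visit1, visit2)
    icc, lb, ub = icc_2way_random_absolute(np.column_stack([v1, v2]))
    r, p = pearson(v1, v2)
    return {"icc": icc, "icc_lb": lb, "icc_ub": ub,
            "pearson_r": r, "pearson_p": p, "n": int(v1.size)}


def compare_devices(test, ref, endpoint: str = "") -> AgreementResult:
    """Full agreement panel for one endpoint: Bland-Altman, error metrics,
    ICC(2,1) with benchmark label, and Pearson correlation."""
    t, rf = _paired(test, ref)
    ba = bland_altman(t, rf)
    em = error_metrics(t, rf)
    icc, lb, ub = icc_2way_random_absolute(np.column_stack([t, rf]))
    r, p = pearson(t, rf)
    return AgreementResult(
        endpoint=endpoint, n=ba["n"], bias=ba["bias"],
        loa_lower=ba["loa_lower"], loa_upper=ba["loa_upper"],
        bias_ci=ba["bias_ci"], loa_lower_ci=ba["loa_lower_ci"],
        loa_upper_ci=ba["loa_upper_ci"], mad=em["mad"], mpe=em["mpe"],
        icc=icc, icc_bounds=(lb, ub), pearson_r=r, pearson_p=p,
        label=classify_agreement(icc))


def agreement_table(merged: pd.DataFrame, endpoints: list[str],
                    test_suffix: str = "_test", ref_suffix: str = "_ref",
                    by: list[str] | None = None) -> pd.DataFrame:
    """Agreement panel per endpoint (optionally per grouping column)."""
    rows = []
    groups = merged.groupby(by) if by else [((), merged)]
    for key, g in groups:
        for ep in endpoints:
            t = g[ep + test_suffix].to_numpy()
            r = g[ep + ref_suffix].to_numpy()
            ok = ~(np.isnan(t) | np.isnan(r))
            if ok.sum() < 3:
                continue
            res = compare_devices(t[ok], r[ok], endpoint=ep).as_row()
            if by:
                key_t = key if isinstance(key, tuple) else (key,)
                res.update(dict(zip(by, key_t)))
            rows.append(res)
    return pd.DataFrame(rows)
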