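"""Inferential layer: mixed-effects device/task models and bout comparisons.

The central model regresses an endpoint on device, task (or environment)
and their interaction as fixed effects, with a subject random intercept and
age as a covariate, fitted by REML.  Fixed-effect terms are tested with
type-III Wald F-tests under sum-to-zero contrasts; pairwise device
differences are reported as least-squares-mean contrasts per task level
with t-based confidence intervals.  No multiplicity correction is applied
by default (an optional Holm adjustment is available).

Degrees of freedom for the F and t statistics use the residual
approximation (n_obs - n_fixed_parameters); with the balanced designs this
package generates, it is close to the Satterthwaite value for
within-subject contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

__all__ = [
    "ModelResult",
    "fit_device_task_model",
    "posthoc_contrasts",
    "fit_environment_model",
    "compare_bout_stats",
]

BOUT_METRICS = ["mean_bout_duration_s", "total_walking_time_s",
                "n_bouts", "total_steps"]


@dataclass
class ModelResult:
    """Fitted mixed model with its ANOVA table and post-hoc contrasts."""

    endpoint: str
    fixed_effects: pd.DataFrame      # estimate, se per coefficient
    anova: pd.DataFrame              # term, F, df_num, df_den, p
    contrasts: pd.DataFrame          # device pair x task: estimate, CI, p
    variance_components: dict        # subject intercept + residual variance
    converged: bool
    df_resid: float
    diagnostics: dict = field(default_factory=dict)


def _prepare(table: pd.DataFrame, factor: str) -> pd.DataFrame:
    df = table.copy()
    for col in ("device", factor, "subject"):
        if col not in df.columns:
            raise ValueError(f"missing required column '{col}'")
        df[col] = df[col].astype(str)
    if "age" not in df.columns:
        df["age"] = 0.0
    df = df.dropna(subset=["value"])
    if df["device"].nunique() < 2:
        raise ValueError("need at least 2 devices")
    if df[factor].nunique() < 2:
        raise ValueError(f"need at least 2 {factor} levels")
    if df["subject"].nunique() < 5:
        raise ValueError("need at least 5 subjects")
    # age must be constant within subject
    if (df.groupby("subject")["age"].nunique() > 1).any():
        raise ValueError("age must be constant within subject")
    return df


def _term_blocks(design_info) -> dict[str, list[int]]:
    """Column indices of each non-intercept term in the fixed-effects design."""
    blocks: dict[str, list[int]] = {}
    for term, sl in design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        blocks[term] = list(range(sl.start, sl.stop))
    return blocks


def fit_device_task_model(table: pd.DataFrame, endpoint: str = "value",
                          factor: str = "task",
                          posthoc_alpha: float = 0.05,
                          adjust: str | None = None) -> ModelResult:
    """REML mixed model: value ~ device * factor + age, random subject intercept.

    ``table`` is long-format with columns subject, age, device, ``factor``
    and value.  Returns type-III Wald F-tests (sum-to-zero contrasts) for
    each fixed term and least-squares-mean device contrasts per factor
    level.  A singular fit triggers a warning and a refit with a minimal
    variance structure, flagged in the diagnostics.
    """
    df = _prepare(table, factor)
    formula = f"value ~ C(device, Sum) * C({factor}, Sum) + age"
    if df["age"].nunique() == 1:
        formula = f"value ~ C(device, Sum) * C({factor}, Sum)"

    converged, flagged = True, False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df["subject"])
        try:
            fit = model.fit(reml=True)
            converged = bool(fit.converged)
        except Exception:
            converged = False
            fit = None
        if fit is None or not converged:
            flagged = True
            warnings.warn("singular or non-converged fit; refitting with "
                          "free=diagonal variance structure")
            from statsmodels.regression.mixed_linear_model import MixedLMParams
            free = MixedLMParams.from_components(
                fe_params=np.ones(model.exog.shape[1]), cov_re=np.eye(1))
            fit = model.fit(reml=True, free=free)

    design_info = model.data.design_info
    beta = np.asarray(fit.fe_params)
    cov = np.asarray(fit.cov_params())[:len(beta), :len(beta)]
    n_obs = len(df)
    df_resid = n_obs - len(beta)

    anova_rows = []
    for term, cols in _term_blocks(design_info).items():
        L = np.zeros((len(cols), len(beta)))
        for i, c in enumerate(cols):
            L[i, c] = 1.0
        lb = L @ beta
        lvl = L @ cov @ L.T
        try:
            fstat = float(lb @ np.linalg.solve(lvl, lb)) / len(cols)
        except np.linalg.LinAlgError:
            fstat = np.nan
        p = float(stats.f.sf(fstat, len(cols), df_resid))
        name = (term.replace("C(device, Sum)", "device")
                .replace(f"C({factor}, Sum)", factor))
        anova_rows.append({"term": name, "F": fstat, "df_num": len(cols),
                           "df_den": df_resid, "p": p})
    anova = pd.DataFrame(anova_rows)

    fe = pd.DataFrame({"estimate": beta,
                       "se": np.sqrt(np.diag(cov))},
                      index=design_info.column_names)
    varcomps = {"subject_intercept_var": float(np.asarray(fit.cov_re).ravel()[0]),
                "residual_var": float(fit.scale)}
    result = ModelResult(endpoint=endpoint, fixed_effects=fe, anova=anova,
                         contrasts=pd.DataFrame(),
                         variance_components=varcomps, converged=converged,
                         df_resid=df_resid,
                         diagnostics={"refit_simplified": flagged,
                                      "formula": formula, "factor": factor,
                                      "n_obs": n_obs})
    result.contrasts = posthoc_contrasts(result, df, design_info, beta, cov,
                                         factor=factor, alpha=posthoc_alpha,
                                         adjust=adjust)
    result.diagnostics["_design_info"] = design_info
    return result


def posthoc_contrasts(result: ModelResult, df: pd.DataFrame, design_info,
                      beta: np.ndarray, cov: np.ndarray, factor: str = "task",
                      alpha: float = 0.05,
                      adjust: str | None = None) -> pd.DataFrame:
    """Least-squares-mean device differences per factor level.

    For each device pair (d1, d2) and each level of ``factor``, the contrast
    is the difference of model-predicted means at that level with age held
    at its sample mean.  CI half-width is t_crit * SE with residual df.
    ``adjust='holm'`` applies a Holm correction across the contrast family.
    """
    from patsy import build_design_matrices

    devices = sorted(df["device"].unique())
    levels = sorted(df[factor].unique())
    age_mean = float(df["age"].mean())
    tcrit = stats.t.ppf(1 - alpha / 2, result.df_resid)
    rows = []
    for i in range(len(devices)):
        for j in range(i + 1, len(devices)):
            d1, d2 = devices[i], devices[j]
            for lev in levels:
                pred = pd.DataFrame({"device": [d1, d2], factor: [lev, lev],
                                     "age": [age_mean, age_mean]})
                (X,) = build_design_matrices([design_info], pred)
                c = np.asarray(X)[0] - np.asarray(X)[1]
                est = float(c @ beta)
                se = float(np.sqrt(c @ cov @ c))
                tstat = est / se if se > 0 else 0.0
                p = float(2 * stats.t.sf(abs(tstat), result.df_resid))
                rows.append({"device_1": d1, "device_2": d2, factor: lev,
                             "estimate": est, "se": se,
                             "ci_lower": est - tcrit * se,
                             "ci_upper": est + tcrit * se,
                             "t": tstat, "p": p})
    out = pd.DataFrame(rows)
    if adjust == "holm" and not out.empty:
        order = np.argsort(out["p"].to_numpy())
        m = len(out)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * out["p"].iloc[idx])
            adj[idx] = min(1.0, running)
        out["p_adjusted"] = adj
    return out


def fit_environment_model(table: pd.DataFrame, endpoint: str = "value",
                          **kw) -> ModelResult:
    """Device x environment mixed model (in-lab vs outside-lab sessions)."""
    return fit_device_task_model(table, endpoint=endpoint,
                                 factor="environment", **kw)


def compare_bout_stats(chest: pd.DataFrame, lumbar: pd.DataFrame,
                       metrics: list[str] | None = None) -> pd.DataFrame:
    """Paired t-tests on per-subject bout statistics, chest vs lumbar.

    Both tables must carry a ``subject`` column plus the bout metrics
    (visit-averaged).  All-zero differences give t = 0, p = 1 exactly.
    """
    metrics = metrics or BOUT_METRICS
    merged = chest.merge(lumbar, on="subject", suffixes=("_chest", "_lumbar"))
    if len(merged) < 3:
        raise ValueError("paired comparison needs at least 3 subjects")
    n = len(merged)
    tcrit = stats.t.ppf(0.975, n - 1)
    rows = []
    for m in metrics:
        d = (merged[f"{m}_chest"] - merged[f"{m}_lumbar"]).to_numpy(dtype=float)
        mean_d = float(d.mean())
        sd = float(d.std(ddof=1))
        if sd == 0:
            tstat, p = (0.0, 1.0) if mean_d == 0 else (np.inf * np.sign(mean_d), 0.0)
            se = 0.0
        else:
            se = sd / np.sqrt(n)
            tstat = mean_d / se
            p = float(2 * stats.t.sf(abs(tstat), n - 1))
        rows.append({"metric": m, "n": n, "mean_difference": mean_d,
                     "ci_lower": mean_d - tcrit * se,
                     "ci_upper": mean_d + tcrit * se,
                     "t": float(tstat), "p": p})
    return pd.DataFrame(rows)
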