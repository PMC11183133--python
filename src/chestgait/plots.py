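"""Agreement plot artifacts: Bland-Altman and scatter with regression band.

These figures annotate the numbers computed by :mod:`chestgait.agreement`;
they are emitted as files and carry no additional tested behaviour.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .agreement import bland_altman, pearson  # noqa: E402

__all__ = ["plot_bland_altman", "plot_scatter"]


def plot_bland_altman(test, ref, path: str | Path, title: str = "",
                      units: str = "") -> None:
    test = np.asarray(test, dtype=float)
    ref = np.asarray(ref, dtype=float)
    ba = bland_altman(test, ref)
    mean = (test + ref) / 2
    diff = test - ref
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(mean, diff, s=18, color="k", zorder=3)
    ax.axhline(ba["bias"], color="tab:blue", label=f"bias {ba['bias']:.3f}")
    for lo_hi in ("loa_lower", "loa_upper"):
        ax.axhline(ba[lo_hi], color="tab:red")
    for ci in ("bias_ci", "loa_lower_ci", "loa_upper_ci"):
        for v in ba[ci]:
            ax.axhline(v, color="gray", linestyle="--", linewidth=0.6)
    ax.axhline(0.0, color="tab:green", linewidth=0.8)
    ax.set_xlabel(f"mean of methods {units}".strip())
    ax.set_ylabel(f"difference (test - reference) {units}".strip())
    ax.set_title(title)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_scatter(test, ref, path: str | Path, title: str = "",
                 units: str = "") -> None:
    test = np.asarray(test, dtype=float)
    ref = np.asarray(ref, dtype=float)
    r, p = pearson(test, ref)
    slope, intercept = np.polyfit(ref, test, 1)
    xs = np.linspace(ref.min(), ref.max(), 50)
    # pointwise 95% band for the regression line
    n = ref.size
    resid = test - (slope * ref + intercept)
    s2 = float(resid @ resid) / (n - 2)
    xbar = ref.mean()
    sxx = float(np.sum((ref - xbar) ** 2))
    se_line = np.sqrt(s2 * (1.0 / n + (xs - xbar) ** 2 / sxx))
    from scipy import stats as _st
    tcrit = _st.t.ppf(0.975, n - 2)
    yhat = slope * xs + intercept
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ref, test, s=18, color="k", zorder=3)
    ax.plot(xs, yhat, color="tab:blue")
    ax.fill_between(xs, yhat - tcrit * se_line, yhat + tcrit * se_line,
                    color="gray", alpha=0.3)
    lims = [min(ref.min(), test.min()), max(ref.max(), test.max())]
    ax.plot(lims, lims, color="tab:green", linewidth=0.8, linestyle=":")
    ax.set_xlabel(f"reference {units}".strip())
    ax.set_ylabel(f"test {units}".strip())
    ax.set_title(f"{title}  R={r:.3f} (p={p:.2g})".strip())
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
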