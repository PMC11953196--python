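"""Optional figure output (requires matplotlib).

Two plot styles mirror the cohort report: T0-vs-T1 box plots for the outer
retinal defect lengths and visual acuity, and the index-vs-BCVA-change
scatter with its least-squares fit.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .stats import univariate_regression, wilcoxon_change_test


def _pyplot():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def change_boxplots(scored: pd.DataFrame, path: str | Path) -> None:
    """Box plots of EZ defect, ELM defect, and BCVA at baseline vs follow-up."""
    plt = _pyplot()
    panels = [
        ("EZ defect [um]", "ez_t0_um", "ez_t1_um"),
        ("ELM defect [um]", "elm_t0_um", "elm_t1_um"),
        ("BCVA [logMAR]", "bcva_t0_logmar", "bcva_t1_logmar"),
    ]
    fig, axes = plt.subplots(1, 3, figsize=(10, 3.5))
    for ax, (title, t0_col, t1_col) in zip(axes, panels):
        t0 = scored[t0_col].dropna()
        t1 = scored[t1_col].dropna()
        ax.boxplot([t0, t1], tick_labels=["T0", "T1"])
        try:
            p = wilcoxon_change_test(t0, t1).p_value
            ax.set_title(f"{title}\np = {p:.3g}", fontsize=9)
        except ValueError:
            ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def regression_scatter(scored: pd.DataFrame, path: str | Path) -> None:
    """Index vs |Δ-BCVA| scatter with the univariate least-squares fit."""
    plt = _pyplot()
    x = scored["piin"]
    y = scored["delta_bcva_logmar"]
    fit = univariate_regression(x, y)
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.scatter(x, y, s=12, alpha=0.7)
    xs = [float(x.min()), float(x.max())]
    ax.plot(xs, [fit.intercept + fit.slope * v for v in xs], color="C3")
    ax.set_xlabel("integrity index")
    ax.set_ylabel("|d-BCVA| [logMAR]")
    ax.set_title(
        f"adj. R2 = {fit.adjusted_r2:.3f}, slope p = {fit.slope_p_value:.3g}",
        fontsize=9,
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
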