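"""Figure rendering for pipeline outputs.

Each figure is produced from the tabular artifacts written by the
pipeline stages; a missing artifact skips that figure with a log entry
rather than failing the run.  The spatial-effect figure is a per-region
bar chart of the ICAR posterior medians (map rendering is out of scope).
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

log = logging.getLogger("u5trends")

__all__ = ["render_figures"]


def _save(fig, path: Path):
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _raw_vs_smoothed(df: pd.DataFrame, path: Path):
    fig, axes = plt.subplots(1, 2, figsize=(11, 4.5), sharey=True)
    for region, block in df.groupby("region"):
        axes[0].plot(block.year, block.raw, lw=1, alpha=0.8, label=region)
        axes[1].plot(block.year, block.smoothed, lw=1.5, label=region)
    axes[0].set_title("(A) Raw estimates")
    axes[1].set_title("(B) Smoothed estimates")
    for ax in axes:
        ax.set_xlabel("Year")
    axes[0].set_ylabel("U5MR per 1000 live births")
    axes[1].legend(fontsize=7, ncol=2)
    _save(fig, path)


def _mean_curve(df: pd.DataFrame, path: Path):
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.fill_between(df.grid, df.lower, df.upper, alpha=0.3, label="95% CI")
    ax.plot(df.grid, df["mean"], lw=2, label="mean curve")
    ax.set_xlabel("Year")
    ax.set_ylabel("U5MR per 1000 live births")
    ax.legend()
    _save(fig, path)


def _fanova_effects(df: pd.DataFrame, path: Path):
    betas = [c for c in df.columns if c.startswith("beta_")]
    ncol = 3
    nrow = -(-(len(betas) + 1) // ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(11, 2.8 * nrow), sharex=True)
    axes = axes.ravel()
    axes[0].plot(df.grid, df.mu)
    axes[0].set_title("grand mean")
    for ax, col in zip(axes[1:], betas):
        ax.plot(df.grid, df[col])
        ax.axhline(0, color="grey", lw=0.5)
        ax.set_title(col.removeprefix("beta_"), fontsize=9)
    for ax in axes[len(betas) + 1:]:
        ax.set_visible(False)
    _save(fig, path)


def _fanova_ftest(df: pd.DataFrame, path: Path):
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.plot(df.grid, df.F_observed, color="red", lw=2, label="observed F")
    ax.plot(df.grid, df.pointwise_crit, color="black", ls="--", label="pointwise 0.05 critical value")
    ax.axhline(df.max_crit.iloc[0], color="blue", ls=":", label="max critical value")
    ax.set_xlabel("Year")
    ax.set_ylabel("F statistic")
    ax.legend()
    _save(fig, path)


def _phi_bar(df: pd.DataFrame, path: Path):
    phi = df[df.effect == "phi"].sort_values("level")
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.bar(phi.level, phi["median"], yerr=[phi["median"] - phi.lower, phi.upper - phi["median"]],
           capsize=3, color="tab:blue", alpha=0.8)
    ax.axhline(0, color="black", lw=0.8)
    ax.set_ylabel("posterior median spatial effect (logit scale)")
    ax.tick_params(axis="x", rotation=45)
    _save(fig, path)


def _gamma_trajectory(df: pd.DataFrame, path: Path):
    g = df[df.effect == "gamma"]
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.fill_between(g.level.astype(float), g.lower, g.upper, alpha=0.3)
    ax.plot(g.level.astype(float), g["median"], lw=2)
    ax.axhline(0, color="grey", lw=0.6)
    ax.set_xlabel("Year")
    ax.set_ylabel("structured temporal effect (logit scale)")
    _save(fig, path)


def _forecast(hist: pd.DataFrame, fc: pd.DataFrame, sdg: float, path: Path):
    fig, ax = plt.subplots(figsize=(8.5, 5))
    for region, block in hist.groupby("region"):
        line, = ax.plot(block.year, block["median"], lw=1.4, label=region)
        f = fc[fc.region == region]
        if len(f):
            ax.plot(f.year, f["median"], lw=1.4, ls="--", color=line.get_color())
            ax.fill_between(f.year, f.lower, f.upper, alpha=0.12, color=line.get_color())
    ax.axhline(sdg, color="black", ls="-.", lw=1.2, label=f"SDG target ({sdg:g}/1000)")
    ax.set_xlabel("Year")
    ax.set_ylabel("U5MR per 1000 live births")
    ax.legend(fontsize=7, ncol=2)
    _save(fig, path)


def render_figures(artifact_dir, sdg_threshold: float = 25.0) -> list[Path]:
    """Render every figure whose input tables exist under ``artifact_dir``."""
    out = Path(artifact_dir)
    figdir = out / "figures"
    figdir.mkdir(exist_ok=True)
    written = []

    jobs = [
        ("fitted_curves.csv", "raw_vs_smoothed.png",
         lambda df, p: _raw_vs_smoothed(df, p)),
        ("mean_curve.csv", "mean_curve.png", lambda df, p: _mean_curve(df, p)),
        ("fanova_effects.csv", "fanova_effects.png", lambda df, p: _fanova_effects(df, p)),
        ("fanova_f.csv", "fanova_ftest.png", lambda df, p: _fanova_ftest(df, p)),
        ("posterior_effects_rw2.csv", "phi_spatial_effects.png", lambda df, p: _phi_bar(df, p)),
        ("posterior_effects_rw2.csv", "gamma_trajectory.png", lambda df, p: _gamma_trajectory(df, p)),
    ]
    for src, dst, fn in jobs:
        src_path = out / src
        if not src_path.exists():
            log.warning("[report] missing %s; skipping %s", src, dst)
            continue
        fn(pd.read_csv(src_path), figdir / dst)
        written.append(figdir / dst)

    hist_path, fc_path = out / "posterior_u5mr_rw2.csv", out / "forecast.csv"
    if hist_path.exists() and fc_path.exists():
        _forecast(pd.read_csv(hist_path), pd.read_csv(fc_path), sdg_threshold,
                  figdir / "forecast.png")
        written.append(figdir / "forecast.png")
    else:
        log.warning("[report] missing posterior/forecast tables; skipping forecast figure")
    return written
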