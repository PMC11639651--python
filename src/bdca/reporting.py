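"""File outputs and plots for decision-curve runs.

Every run emits a manifest (config hash, seed, library versions) so outputs
can be reproduced bit-for-bit, a tidy curve summary, the full interrogation
table, and a long-format draw export (threshold, strategy, draw, nb).
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .interrogation import (
    TREAT_ALL,
    TREAT_NONE,
    DecisionCurveSet,
    InterrogationResult,
    interrogate,
    summarize_curves,
)

__all__ = [
    "write_run_outputs",
    "export_draws_long",
    "export_plots",
]


def _versions() -> dict:
    import arviz
    import emcee
    import scipy

    from . import __version__

    return {
        "bdca": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "emcee": emcee.__version__,
        "arviz": arviz.__version__,
        "python": platform.python_version(),
    }


def export_draws_long(curves: DecisionCurveSet, path: Path) -> None:
    """Write all net-benefit draws in long format (threshold, strategy, draw, nb)."""
    s_count, t_count, m = curves.nb_draws.shape
    frames = []
    for i, name in enumerate(curves.strategies):
        df = pd.DataFrame(
            {
                "threshold": np.repeat(curves.grid.thresholds, m),
                "strategy": name,
                "draw": np.tile(np.arange(m), t_count),
                "nb": curves.nb_draws[i].ravel(),
            }
        )
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_run_outputs(
    curves: DecisionCurveSet,
    outdir: Path,
    config: dict,
    result: InterrogationResult | None = None,
    diagnostics: dict | None = None,
    plots: bool = False,
    draws: bool = True,
) -> InterrogationResult:
    """Write the standard output bundle for one analysis run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = result or interrogate(curves)
    summarize_curves(curves).to_csv(outdir / "curves.csv", index=False)
    result.to_csv(outdir / "interrogation.csv")
    result.to_json(outdir / "interrogation.json")
    if draws:
        export_draws_long(curves, outdir / "nb_draws.csv")
    if diagnostics:
        serializable = {
            f"{k[0]}@{k[1]}" if isinstance(k, tuple) else str(k): v
            for k, v in diagnostics.items()
        }
        (outdir / "mcmc_diagnostics.json").write_text(
            json.dumps(serializable, indent=1, default=str)
        )
    config_text = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "versions": _versions(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    if plots:
        export_plots(outdir)
    return result


def _require_columns(df: pd.DataFrame, cols: list[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def export_plots(results_dir: Path, outdir: Path | None = None) -> list[Path]:
    """Render decision-curve, probability, pairwise and EVPI panels.

    Reads the CSV outputs of :func:`write_run_outputs` back from disk, so the
    plots always display exactly what was exported.
    """
    results_dir = Path(results_dir)
    outdir = Path(outdir) if outdir is not None else results_dir
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    curves_path = results_dir / "curves.csv"
    interr_path = results_dir / "interrogation.csv"
    curves = pd.read_csv(curves_path)
    _require_columns(curves, ["threshold", "strategy", "nb_mean", "nb_lo", "nb_hi"], curves_path)
    interr = pd.read_csv(interr_path)
    _require_columns(
        interr, ["threshold", "strategy", "p_useful", "p_best", "evpi"], interr_path
    )

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for name, df in curves.groupby("strategy"):
        df = df.sort_values("threshold")
        style = {"ls": "--"} if name in (TREAT_ALL, TREAT_NONE) else {}
        ax.plot(df.threshold, df.nb_mean, label=name, **style)
        if name != TREAT_NONE:
            ax.fill_between(df.threshold, df.nb_lo, df.nb_hi, alpha=0.2)
    ax.set_xlabel("decision threshold")
    ax.set_ylabel("net benefit")
    ax.legend(frameon=False, fontsize=8)
    lo = curves.nb_lo.min()
    ax.set_ylim(max(lo, -0.15), None)
    path = outdir / "decision_curves.png"
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    written.append(path)

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.8), sharey=True)
    for ax_, col, title in zip(axes, ["p_useful", "p_best"], ["P(useful)", "P(best)"]):
        for name, df in interr.groupby("strategy"):
            df = df.sort_values("threshold")
            if df[col].notna().any():
                ax_.plot(df.threshold, df[col], label=name)
        ax_.set_title(title)
        ax_.set_xlabel("decision threshold")
        ax_.set_ylim(-0.02, 1.02)
    axes[0].set_ylabel("posterior probability")
    axes[1].legend(frameon=False, fontsize=8)
    path = outdir / "probabilities.png"
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    written.append(path)

    evpi_df = interr.drop_duplicates("threshold").sort_values("threshold")
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(evpi_df.threshold, evpi_df.evpi)
    ax.set_xlabel("decision threshold")
    ax.set_ylabel("EVPI (net true positives)")
    path = outdir / "evpi.png"
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    written.append(path)

    draws_path = results_dir / "nb_draws.csv"
    if draws_path.exists():
        written.append(_plot_pairwise(draws_path, outdir))
    return written


def _plot_pairwise(draws_path: Path, outdir: Path) -> Path:
    """Pairwise delta density (model vs best non-default competitor) with
    66% and 95% interval bars, at the grid threshold of maximal overlap."""
    draws = pd.read_csv(draws_path)
    _require_columns(draws, ["threshold", "strategy", "draw", "nb"], draws_path)
    models = [s for s in draws.strategy.unique() if s not in (TREAT_ALL, TREAT_NONE)]
    fig, ax = plt.subplots(figsize=(6, 3.5))
    if len(models) >= 2:
        s1, s2 = models[:2]
        t = draws.threshold.max()
        d1 = draws[(draws.strategy == s1) & (draws.threshold == t)].sort_values("draw").nb
        d2 = draws[(draws.strategy == s2) & (draws.threshold == t)].sort_values("draw").nb
        delta = d1.to_numpy() - d2.to_numpy()
        ax.hist(delta, bins=60, density=True, alpha=0.6)
        for lev, lw in ((66, 4), (95, 1.5)):
            lo, hi = np.percentile(delta, [(100 - lev) / 2, 100 - (100 - lev) / 2])
            ax.plot([lo, hi], [0, 0], lw=lw, solid_capstyle="butt", color="k")
        ax.plot(delta.mean(), 0, "o", color="k")
        ax.axvline(0.0, ls=":", color="grey")
        ax.set_xlabel(f"NB({s1}) - NB({s2}) at t={t:g}")
    else:
        ax.text(0.5, 0.5, "needs two model strategies", ha="center", va="center")
    path = outdir / "pairwise_delta.png"
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path
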