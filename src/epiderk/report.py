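"""Summary report rendering for a completed (or partial) pipeline run.

Produces three panel families from a run directory's CSV artifacts:
smoothed per-target depth profiles, permutation-null histograms with their
99 % thresholds and observed statistics, and model-vs-data phospho-ERK
panels from the input fit.  Missing stages are listed rather than fatal;
model depths that failed to reach steady state are flagged.  Rendering is
deterministic: the same inputs produce byte-identical figures.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["render_report"]


def _plot_profiles(run: Path, out: Path) -> str | None:
    src = run / "smoothed_curves.csv"
    if not src.exists():
        return None
    df = pd.read_csv(src)
    fig, ax = plt.subplots(figsize=(7, 4))
    for name, grp in df.groupby("series"):
        ax.plot(grp["u"], grp["fitted_z"], label=name, lw=1.5)
    ax.set_xlabel("layer-normalized distance u")
    ax.set_ylabel("smoothed z-scored intensity")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "profiles.png", dpi=120, metadata={"Software": None})
    plt.close(fig)
    return "profiles.png"


def _plot_nulls(run: Path, out: Path) -> str | None:
    nulls_src, assoc_src = run / "null_samples.csv", run / "associations.csv"
    if not (nulls_src.exists() and assoc_src.exists()):
        return None
    nulls = pd.read_csv(nulls_src)
    assoc = pd.read_csv(assoc_src)
    pairs = assoc.head(6)  # first panels; full table stays in the CSV
    fig, axes = plt.subplots(len(pairs), 2, figsize=(8, 2.2 * len(pairs)),
                             squeeze=False)
    for i, row in enumerate(pairs.itertuples()):
        sel = (nulls["pair_a"] == row.pair_a) & (nulls["pair_b"] == row.pair_b)
        for j, (stat, obs, thr) in enumerate(
            (("pearson", row.pearson_r, (row.null_lo, row.null_hi)),
             ("mi", row.mutual_info, (row.null_mi_hi,)))
        ):
            ax = axes[i][j]
            vals = nulls.loc[sel & (nulls["stat"] == stat), "value"]
            ax.hist(vals, bins=30, color="0.7", density=True)
            for t in thr:
                ax.axvline(t, color="tab:blue", lw=1)
            ax.axvline(obs, color="tab:red", lw=1.5)
            ax.set_title(f"{row.pair_a} vs {row.pair_b} ({stat})", fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "association_nulls.png", dpi=120, metadata={"Software": None})
    plt.close(fig)
    return "association_nulls.png"


def _plot_fit(run: Path, out: Path) -> str | None:
    src = run / "fit_curves.csv"
    if not src.exists():
        return None
    df = pd.read_csv(src)
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.2))
    for ax, name, title in zip(axes, ("erkc", "erkn"),
                               ("cytoplasmic pERK", "nuclear pERK")):
        ax.plot(df["d"], df[f"data_{name}"], "o", color="0.3", label="data")
        ax.plot(df["d"], df[f"model_{name}"], "-", color="tab:red", label="model")
        ax.set_xlabel("model depth d")
        ax.set_ylabel("standardized abundance")
        ax.set_title(title, fontsize=9)
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "model_vs_data.png", dpi=120, metadata={"Software": None})
    plt.close(fig)
    return "model_vs_data.png"


def render_report(run: Path, out: Path) -> Path:
    """Render all available panels and write report.md; returns its path."""
    out.mkdir(parents=True, exist_ok=True)
    panels = {
        "Smoothed spatial profiles": _plot_profiles(run, out),
        "Permutation null distributions": _plot_nulls(run, out),
        "Model vs data (phospho-ERK fit)": _plot_fit(run, out),
    }
    lines = ["# Pipeline report", ""]
    for title, png in panels.items():
        if png:
            lines += [f"## {title}", "", f"![{title}]({png})", ""]
        else:
            lines += [f"## {title}", "", "_stage outputs missing from run directory_", ""]
    sim = run / "spatial_profile.csv"
    if sim.exists():
        prof = pd.read_csv(sim)
        bad = prof.loc[~prof["converged"].astype(bool), "d"].tolist()
        lines += ["## Steady-state convergence", ""]
        if bad:
            lines += [f"Depths not converged (residual >= 1e-6): {bad}", ""]
        else:
            lines += ["All depths reached steady state (residual < 1e-6).", ""]
    path = out / "report.md"
    path.write_text("\n".join(lines))
    return path
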