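"""Figure and table rendering for analyzed cohorts."""

from __future__ import annotations

from pathlib import Path
from typing import List

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import stats as st
from .errors import MetricError


def histogram_figures(table: pd.DataFrame, outdir: Path,
                      bins: int = 40, value_range=(0.0, 2.5)) -> List[Path]:
    """One per-day histogram of subject surface RR by group."""
    paths = []
    df = table.dropna(subset=["surface_rr"])
    for day, sub in df.groupby("day"):
        fig, ax = plt.subplots(figsize=(4.5, 3.2))
        for group, cell in sub.groupby("group"):
            ax.hist(cell["surface_rr"], bins=np.linspace(*value_range, bins + 1),
                    alpha=0.6, label=group)
        ax.set_xlabel("surface redox ratio (NADH/FAD)")
        ax.set_ylabel("subjects")
        ax.set_title(f"day {day}")
        ax.legend()
        p = outdir / f"surface_rr_day{day}.png"
        fig.tight_layout()
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return paths


def scatter_figure(table: pd.DataFrame, outdir: Path) -> Path:
    """Surface RR vs normalized wound area with the least-squares line."""
    df = table.dropna(subset=["surface_rr", "normalized_area"])
    if len(df) < 3:
        raise MetricError("not enough points for the correlation figure")
    res = st.pearson(df["normalized_area"], df["surface_rr"])
    fig, ax = plt.subplots(figsize=(4.5, 3.6))
    for group, cell in df.groupby("group"):
        ax.scatter(cell["normalized_area"], cell["surface_rr"], s=18, label=group)
    xs = np.linspace(df["normalized_area"].min(), df["normalized_area"].max(), 50)
    ax.plot(xs, res.slope * xs + res.intercept, "k-",
            label=f"fit: R²={res.r_squared:.2f}")
    ax.set_xlabel("normalized wound area")
    ax.set_ylabel("surface redox ratio")
    ax.legend(fontsize=8)
    p = outdir / "surface_rr_vs_area.png"
    fig.tight_layout()
    fig.savefig(p, dpi=120)
    plt.close(fig)
    return p


def summary_markdown(summary: pd.DataFrame, outdir: Path) -> Path:
    """Longitudinal mean ± SE table as markdown (one block per marker)."""
    lines = ["# Longitudinal wound assessments", ""]
    for marker, sub in summary.groupby("marker"):
        lines.append(f"## {marker}")
        lines.append("")
        lines.append("| day | group | n | mean ± SE | significant |")
        lines.append("|---|---|---|---|---|")
        for _, r in sub.iterrows():
            se = "—" if pd.isna(r["se"]) else f"{r['se']:.3f}"
            star = "*" if r["significant"] else ""
            lines.append(
                f"| {r['day']} | {r['group']} | {r['n']} | "
                f"{r['mean']:.3f} ± {se} | {star} |")
        lines.append("")
    p = outdir / "summary.md"
    p.write_text("\n".join(lines))
    return p
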