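"""Figure-style reporting: heat maps, bottleneck map, sensitivity slices,
path overlay and transition profiles, rendered from sweep/optimizer tables.

All figures are deterministic functions of the tidy CSV outputs, so any
panel can be regenerated bit-for-bit from config + seeds via the manifest.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def _pivot(table: pd.DataFrame, column: str) -> pd.DataFrame:
    return table.pivot(index="I", columns="A", values=column).sort_index(
        ascending=False)


def _heatmap(ax, grid: pd.DataFrame, title: str, cmap: str = "viridis"):
    im = ax.imshow(grid.values, cmap=cmap, aspect="auto",
                   extent=(-0.05, 1.05, -0.05, 1.05), origin="upper")
    ax.set_xlabel("AI automation intensity A")
    ax.set_ylabel("Data interoperability I")
    ax.set_title(title)
    return im


def render_heatmaps(table: pd.DataFrame, out_dir: Path) -> List[Path]:
    """RTTI and throughput surfaces over the A x I grid."""
    paths = []
    for column, title, cmap in (
        ("mean_rtti_days", "Mean referral-to-treatment interval (days)",
         "magma"),
        ("mean_throughput_per_year", "Annualized throughput (patients/year)",
         "viridis"),
    ):
        fig, ax = plt.subplots(figsize=(5.2, 4.2))
        im = _heatmap(ax, _pivot(table, column), title, cmap)
        fig.colorbar(im, ax=ax)
        fig.tight_layout()
        p = out_dir / f"{column}_heatmap.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        paths.append(p)
    return paths


def render_bottleneck_map(table: pd.DataFrame, out_dir: Path) -> Path:
    """Categorical map of the modal binding constraint per grid cell."""
    pools = sorted(table["modal_bottleneck"].unique())
    code = {p: i for i, p in enumerate(pools)}
    coded = table.assign(code=table["modal_bottleneck"].map(code))
    grid = _pivot(coded, "code")
    fig, ax = plt.subplots(figsize=(6.0, 4.2))
    cmap = plt.get_cmap("tab10", len(pools))
    im = ax.imshow(grid.values, cmap=cmap, vmin=-0.5, vmax=len(pools) - 0.5,
                   aspect="auto", extent=(-0.05, 1.05, -0.05, 1.05),
                   origin="upper")
    ax.set_xlabel("AI automation intensity A")
    ax.set_ylabel("Data interoperability I")
    ax.set_title("Primary bottleneck migration")
    cbar = fig.colorbar(im, ax=ax, ticks=range(len(pools)))
    cbar.ax.set_yticklabels(pools)
    fig.tight_layout()
    p = out_dir / "bottleneck_map.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    return p


def render_utilization_slices(table: pd.DataFrame, out_dir: Path,
                              baseline: float = 0.5) -> List[Path]:
    """Resource-use sensitivity: vary one lever, hold the other at 0.5."""
    util_cols = [c for c in table.columns if c.startswith("util_")]
    paths = []
    for axis, fixed in (("A", "I"), ("I", "A")):
        near = table[np.isclose(table[fixed], baseline)]
        if near.empty:  # grid without a 0.5 line (even resolution)
            continue
        fig, ax = plt.subplots(figsize=(6.0, 4.2))
        sliced = near.sort_values(axis)
        for col in util_cols:
            ax.plot(sliced[axis], sliced[col], label=col[5:], lw=1.4)
        ax.axhline(1.0, ls="--", color="k", lw=0.8, label="max capacity")
        ax.set_xlabel(f"{axis} (with {fixed} = {baseline})")
        ax.set_ylabel("Mean use rate")
        ax.set_ylim(0, 1.08)
        ax.legend(fontsize=7, ncol=2)
        fig.tight_layout()
        p = out_dir / f"utilization_vs_{axis}.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        paths.append(p)
    return paths


def render_path_overlay(table: pd.DataFrame, volatility: pd.DataFrame,
                        paths: Dict[str, List], out_dir: Path) -> Path:
    """Adoption paths drawn over the combined volatility surface."""
    fig, ax = plt.subplots(figsize=(5.6, 4.4))
    grid = volatility.pivot(index="I", columns="A",
                            values="volatility").sort_index(ascending=False)
    im = ax.imshow(grid.values, cmap="Greys", aspect="auto",
                   extent=(-0.05, 1.05, -0.05, 1.05), origin="upper")
    fig.colorbar(im, ax=ax, label="combined volatility")
    colors = {"optimal": "tab:green", "automation_first": "tab:red",
              "interoperability_first": "tab:blue"}
    for name, nodes in paths.items():
        xs = [n[0] for n in nodes]
        ys = [n[1] for n in nodes]
        ax.plot(xs, ys, "-o", ms=3, lw=1.8,
                color=colors.get(name, "tab:orange"), label=name)
    ax.set_xlabel("AI automation intensity A")
    ax.set_ylabel("Data interoperability I")
    ax.set_title("Adoption paths over the volatility landscape")
    ax.legend(fontsize=8)
    fig.tight_layout()
    p = out_dir / "path_overlay.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    return p


def render_transition_profile(profile: List[dict], out_dir: Path,
                              name: str = "optimal") -> Path:
    """Normalized efficiency/throughput/stability vs transition progress."""
    fig, ax = plt.subplots(figsize=(5.6, 4.0))
    xs = [100.0 * row["progress"] for row in profile]
    for key in ("efficiency", "throughput", "stability"):
        ax.plot(xs, [row[key] for row in profile], "-o", ms=3, label=key)
    ax.set_xlabel("Transition progress (%)")
    ax.set_ylabel("Normalized metric")
    ax.set_ylim(-0.02, 1.02)
    ax.set_title(f"Transition profile ({name} path)")
    ax.legend()
    fig.tight_layout()
    p = out_dir / f"transition_profile_{name}.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    return p
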