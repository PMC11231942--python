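"""Plotting: phase-diagram heatmaps, difference maps, range-comparison bar
charts, trajectories and lattice snapshots. PNG output via matplotlib."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import ListedColormap

from .lattice import EMITTER, NONEMITTER, VACANT, LatticeState, Trajectory
from .meanfield import (MeanFieldPhaseDiagram, emission_viability_threshold,
                        emitter_fixation_bound)

__all__ = [
    "FigureSpec", "render_heatmap", "render_difference_map",
    "render_lattice_snapshot", "render_trajectory", "render_bar_comparison",
]


@dataclass(frozen=True)
class FigureSpec:
    """Rendering options shared by the figure functions."""

    out_path: str
    title: str = ""
    cmap: str = "viridis"
    dpi: int = 150
    annotate: bool = False  # print per-cell values on heatmaps
    overlay_boundaries: bool = False  # closed-form regime curves (mean-field)


def _finish(fig, spec: FigureSpec) -> str:
    fig.savefig(spec.out_path, dpi=spec.dpi, bbox_inches="tight")
    plt.close(fig)
    return spec.out_path


def render_heatmap(diagram, spec: FigureSpec) -> str:
    """Heatmap of emitter frequency/density over the (alpha1, alpha2) plane.

    Accepts a lattice ``PhaseDiagram`` (cell_values) or a
    ``MeanFieldPhaseDiagram`` (stable_density). Color scale fixed to [0, 1].
    Optionally overlays the two closed-form regime boundaries
    alpha1 = (alpha2^n p - c)/(alpha2^n p (1-c)) and
    alpha1 = (p - c)/(p (1 - c)).
    """
    values = getattr(diagram, "cell_values", None)
    if values is None:
        values = diagram.stable_density
    a1 = np.asarray(diagram.alpha1_values)
    a2 = np.asarray(diagram.alpha2_values)
    if values.shape != (a2.size, a1.size):
        raise ValueError("diagram values do not match its alpha grids")

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.pcolormesh(a1, a2, values, cmap=spec.cmap, vmin=0.0, vmax=1.0,
                       shading="nearest")
    fig.colorbar(im, ax=ax, label="emitter frequency")
    if spec.annotate:
        for i, y in enumerate(a2):
            for j, x in enumerate(a1):
                if np.isfinite(values[i, j]):
                    ax.text(x, y, f"{values[i, j]:.2f}", ha="center",
                            va="center", fontsize=6, color="w")
    if spec.overlay_boundaries and isinstance(diagram, MeanFieldPhaseDiagram):
        p_, c_, n_ = (diagram.params_base.p, diagram.params_base.c,
                      diagram.params_base.n)
        a2_fine = np.linspace(a2.min(), a2.max(), 200)
        lower = np.array([emitter_fixation_bound(p_, c_, a, n_)
                          for a in a2_fine])
        ok = (lower > a1.min()) & (lower < a1.max())
        ax.plot(lower[ok], a2_fine[ok], "w--", lw=1)
        thr = emission_viability_threshold(p_, c_)
        if a1.min() < thr < a1.max():
            ax.axvline(thr, color="w", ls="--", lw=1)
    ax.set_xlabel(r"$\alpha_1$ (intra-communication)")
    ax.set_ylabel(r"$\alpha_2$ (inter-communication)")
    ax.set_title(spec.title)
    return _finish(fig, spec)


def render_difference_map(comparison, spec: FigureSpec) -> str:
    """Symmetric red/blue map of a cellwise mean-frequency difference."""
    diff = comparison.difference
    a1 = np.asarray(comparison.alpha1_values)
    a2 = np.asarray(comparison.alpha2_values)
    lim = max(np.abs(diff).max(), 1e-9)
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.pcolormesh(a1, a2, diff, cmap="RdBu_r", vmin=-lim, vmax=lim,
                       shading="nearest")
    fig.colorbar(im, ax=ax,
                 label=f"{comparison.label_a} − {comparison.label_b}")
    ax.set_xlabel(r"$\alpha_1$")
    ax.set_ylabel(r"$\alpha_2$")
    ax.set_title(spec.title)
    return _finish(fig, spec)


# Emitters dark blue, non-emitters white, vacant light gray.
_SNAPSHOT_CMAP = ListedColormap(["#d9d9d9", "#1f4e9c", "#ffffff"])


def render_lattice_snapshot(state: LatticeState, spec: FigureSpec) -> str:
    """One cell per site; emitters dark blue, non-emitters white, vacant
    gray."""
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(state.sites, cmap=_SNAPSHOT_CMAP, vmin=VACANT, vmax=NONEMITTER,
              interpolation="nearest")
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title(spec.title)
    return _finish(fig, spec)


def render_trajectory(traj: Trajectory, spec: FigureSpec) -> str:
    """Strategy counts over time for one simulation run."""
    fig, ax = plt.subplots(figsize=(5, 3))
    t = traj.steps_recorded
    ax.plot(t, traj.counts[:, 0], label="emitters", color="#1f4e9c")
    ax.plot(t, traj.counts[:, 1], label="non-emitters", color="#c08a00")
    ax.plot(t, traj.counts[:, 2], label="vacant", color="#999999")
    ax.set_xlabel("step")
    ax.set_ylabel("sites")
    ax.legend(frameon=False)
    ax.set_title(spec.title)
    return _finish(fig, spec)


def render_bar_comparison(summary, spec: FigureSpec,
                          value_col: str = "mean_frequency",
                          err_col: str = "sd_frequency") -> str:
    """Bar chart with sd error bars, one bar per (r_bvoc, r_d) combination."""
    labels = [f"rBVOC={r.r_bvoc}, rD={r.r_d}" for r in summary.itertuples()]
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.bar(labels, summary[value_col], yerr=summary[err_col], capsize=4,
           color=["#e8b004", "#e87d04", "#e8b004", "#e87d04"][:len(labels)])
    ax.set_ylabel("mean emitter frequency")
    ax.set_ylim(0, 1)
    ax.tick_params(axis="x", rotation=20)
    ax.set_title(spec.title)
    return _finish(fig, spec)
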