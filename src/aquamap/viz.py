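"""Diagnostic plots: sampling schedule, soft-gating, parameter maps.

Thin matplotlib helpers; every function returns the figure so callers can
save or show it.  Parameter maps use perceptually uniform colormaps in the
spirit of current relaxometry-visualization recommendations (approximated
here by matplotlib's built-in uniform maps: T1 -> "inferno"-like warm scale,
T2 -> "viridis"-like cool scale).
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_schedule", "plot_gating", "plot_maps", "relaxometry_colormap"]


def relaxometry_colormap(kind: str):
    """Colormap for quantitative maps: kind in {'t1', 't2', 'pd'}."""
    return {
        "t1": plt.get_cmap("inferno"),
        "t2": plt.get_cmap("viridis"),
        "pd": plt.get_cmap("gray"),
    }[kind]


def plot_schedule(sampling, n_shots: int = 8):
    """ky-kz profile walk of the first shots, colored by acquisition order."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for i in range(min(n_shots, sampling.n_shots)):
        c = sampling.coords[i]
        ax.plot(c[:, 0], c[:, 1], "-o", ms=2, lw=0.7, alpha=0.8,
                label=f"shot {i}" if i < 4 else None)
    ny, nz = sampling.grid_shape
    th = np.linspace(0, 2 * np.pi, 200)
    ax.plot(ny / 2 * np.cos(th), nz / 2 * np.sin(th), "k--", lw=0.5)
    ax.set_xlabel("ky")
    ax.set_ylabel("kz")
    ax.set_title(f"CASPR schedule (R = {sampling.acceleration:g})")
    ax.legend(loc="upper right", fontsize=7)
    ax.set_aspect("equal")
    return fig


def plot_gating(trace_amplitude, states, weights=None):
    """Surrogate trace, motion-state medoids and the soft-gating Gaussian."""
    m = np.asarray(getattr(trace_amplitude, "amplitude", trace_amplitude))
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.2))
    ax1.plot(m, lw=0.6)
    for med in states.medoids:
        ax1.axhline(med, color="C1", lw=0.8, ls="--")
    ax1.axhline(states.reference, color="C2", lw=1.2,
                label="reference (end-expiration)")
    ax1.set_xlabel("profile index")
    ax1.set_ylabel("amplitude")
    ax1.legend(fontsize=7)
    grid = np.linspace(m.min(), m.max(), 400)
    if states.sigma > 0:
        g = np.exp(-((grid - states.reference) ** 2) / (2 * states.sigma**2))
        ax2.plot(grid, g, label="soft-gating weight")
    if weights is not None:
        w = np.asarray(getattr(weights, "weights", weights))
        ax2.plot(m, w, ".", ms=2, alpha=0.4, label="per profile")
    ax2.set_xlabel("amplitude")
    ax2.set_ylabel("weight")
    ax2.legend(fontsize=7)
    fig.tight_layout()
    return fig


def plot_maps(maps, z: int | None = None):
    """wT1 / wT2 / water-amplitude slices of a ParameterMaps object."""
    z = maps.wt1.shape[2] // 2 if z is None else z
    fig, axes = plt.subplots(1, 3, figsize=(11, 3.5))
    for ax, (name, vol, kind) in zip(axes, [
        ("wT1 (ms)", np.where(maps.mask, maps.wt1, np.nan), "t1"),
        ("wT2 (ms)", np.where(maps.mask, maps.wt2, np.nan), "t2"),
        ("|PD water|", np.abs(maps.pd_water), "pd"),
    ]):
        im = ax.imshow(vol[:, :, z].T, origin="lower",
                       cmap=relaxometry_colormap(kind))
        ax.set_title(name)
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    return fig
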