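"""Best-effort figure export for simulation results (maps, sweeps, EFROC)."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_material_maps(maps, path: str, title: str = "") -> None:
    """Side-by-side Al and PMMA thickness maps."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, img, label in zip(axes, (maps.al_map, maps.pmma_map),
                              ("Al (mm)", "PMMA (mm)")):
        im = ax.imshow(img, cmap="gray")
        ax.set_title(label)
        fig.colorbar(im, ax=ax, shrink=0.8)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_drf(drf, path: str) -> None:
    """Log-scale DRF matrix plus example incident-energy rows."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    im = ax1.imshow(np.log10(np.maximum(drf.R, 1e-8)), aspect="auto",
                    origin="lower",
                    extent=[drf.detected_energies[0], drf.detected_energies[-1],
                            drf.incident_energies[0], drf.incident_energies[-1]])
    ax1.set_xlabel("detected energy (keV)")
    ax1.set_ylabel("incident energy (keV)")
    fig.colorbar(im, ax=ax1, label="log10 R")
    for e in (60, 80, 100):
        i = int(np.where(drf.incident_energies == e)[0][0])
        ax2.plot(drf.detected_energies, drf.R[i], label=f"{e} keV")
    ax2.set_xlabel("detected energy (keV)")
    ax2.set_ylabel("response")
    ax2.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_accuracy_sweep(df, path: str, metric: str = "rmse_mm") -> None:
    """Per-model metric versus dose, one panel per calibration grid size."""
    grids = sorted(df["grid"].unique())
    fig, axes = plt.subplots(1, len(grids), figsize=(4 * len(grids), 3.5),
                             sharey=True, squeeze=False)
    for ax, g in zip(axes[0], grids):
        sub = df[df["grid"] == g]
        for model, grp in sub.groupby("model"):
            means = grp.groupby("dose_mAs")[metric].mean()
            ax.plot(means.index, means.values, "o-", label=model)
        ax.set_xscale("log")
        ax.set_title(f"grid {g}x{g}")
        ax.set_xlabel("dose (mAs)")
    axes[0][0].set_ylabel(metric)
    axes[0][0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_efroc_sweep(df, path: str) -> None:
    """A_FE versus dose with Hanley–McNeil error bars, one panel per task."""
    tasks = sorted(df["task"].unique())
    fig, axes = plt.subplots(1, len(tasks), figsize=(4.5 * len(tasks), 3.5),
                             sharey=True, squeeze=False)
    for ax, task in zip(axes[0], tasks):
        sub = df[df["task"] == task]
        for model, grp in sub.groupby("model"):
            grp = grp.sort_values("dose_mAs")
            ax.errorbar(grp["dose_mAs"], grp["A_FE"], yerr=grp["sigma"],
                        fmt="o-", capsize=3, label=model)
        ax.set_xscale("log")
        ax.set_ylim(-0.05, 1.05)
        ax.set_title(task)
        ax.set_xlabel("dose (mAs)")
    axes[0][0].set_ylabel("A_FE")
    axes[0][0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
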