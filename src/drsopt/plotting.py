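"""Quick-look plots for SNR surfaces and spectra."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

__all__ = ["plot_snr_surface", "plot_spectra"]


def plot_snr_surface(surface, path: str | Path | None = None):
    """Heat map of a detector-grid SNR surface; returns the figure."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax_vals = surface.grid.axis()
    im = ax.pcolormesh(ax_vals, ax_vals, surface.snr.T, shading="nearest",
                       cmap="viridis")
    bx, by = surface.argmax_position
    ax.plot(bx, by, "r+", markersize=10, label="max SNR")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_title(f"SNR surface (max {surface.max_snr:.3g})")
    ax.legend(loc="upper right")
    fig.colorbar(im, ax=ax, label="SNR")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_spectra(spectra, labels=None, path: str | Path | None = None):
    """Overlay spectra (vertical offsets) for inspection."""
    fig, ax = plt.subplots(figsize=(6, 4))
    offset = 0.0
    for i, spec in enumerate(spectra):
        lbl = labels[i] if labels else spec.meta.get("label", f"spectrum {i}")
        ax.plot(spec.wavenumbers, spec.counts + offset, lw=0.8, label=lbl)
        offset += 1.1 * spec.counts.max()
    ax.set_xlabel("wavenumber (cm$^{-1}$)")
    ax.set_ylabel("counts (offset)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
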