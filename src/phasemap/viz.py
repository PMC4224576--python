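"""PNG and plain-text export of grids and series.

Colour conventions follow the analysis figures this pipeline produces:
phase masks red (Lo) / blue (Ld), match maps red / blue / white (mismatch),
thickness fields a topographic palette (blue-green thin, yellow-brown
thick).
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
import numpy as np

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
from matplotlib.colors import ListedColormap  # noqa: E402

MASK_CMAP = ListedColormap(["#c0392b", "#2980b9"])          # Lo red, Ld blue
MATCH_CMAP = ListedColormap(["#c0392b", "#2980b9", "#ffffff"])


def save_matrix_txt(values: np.ndarray, path: str | Path, fmt: str = "%.6g") -> None:
    """Plain-text matrix dump (one grid row per line)."""
    np.savetxt(path, np.asarray(values), fmt=fmt)


def _imshow(values, cmap, path, vmin=None, vmax=None, colorbar=False,
            title=None):
    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(np.asarray(values).T, origin="lower", cmap=cmap,
                   vmin=vmin, vmax=vmax, interpolation="nearest")
    ax.set_xlabel("x (Å)")
    ax.set_ylabel("y (Å)")
    if title:
        ax.set_title(title)
    if colorbar:
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def save_mask_png(mask, path: str | Path) -> None:
    _imshow(mask.values.astype(int), MASK_CMAP, path, vmin=0, vmax=1,
            title=f"phase mask ({mask.leaflet or '?'})")


def save_match_png(match, path: str | Path) -> None:
    _imshow(match.values, MATCH_CMAP, path, vmin=0, vmax=2,
            title="leaflet match")


def save_density_png(density, path: str | Path) -> None:
    _imshow(density.values, "viridis", path, colorbar=True,
            title=f"{density.species or 'density'} ({density.leaflet or '?'})")


def save_thickness_png(thickness, path: str | Path) -> None:
    _imshow(thickness.values, "terrain", path, colorbar=True,
            title="bilayer thickness (Å)")


def save_loglog_fit_png(series, fit, path: str | Path) -> None:
    """Log-log plot of one metric series with its power-law fit line."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.loglog(series.times, series.values, "o", ms=4, label=series.metric)
    t = np.linspace(fit.window[0], fit.window[1], 50)
    ax.loglog(t, fit.prefactor * t ** fit.alpha, "-",
              label=f"t^{fit.alpha:.2f} (r² = {fit.r_squared:.3f})")
    ax.set_xlabel("t (µs)")
    ax.set_ylabel(series.metric)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
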