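"""Optional matplotlib helpers (field maps and snapshot scatters).

Thin visualization layer outside the tested contract; requires the
``plot`` extra.
"""

from __future__ import annotations

import numpy as np


def plot_field_map(fg, plane_index: int = 0, ax=None):
    """Grayscale |E_rms| map of one z-plane with electrode outlines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    mag = np.sqrt(fg.erms_sq[:, :, plane_index]).T
    extent = [fg.grid.x[0] * 1e6, fg.grid.x[-1] * 1e6,
              fg.grid.y[0] * 1e6, fg.grid.y[-1] * 1e6]
    im = ax.imshow(mag, origin="lower", extent=extent, cmap="gray")
    if fg.electrode_sign is not None:
        ax.contour(fg.grid.x * 1e6, fg.grid.y * 1e6,
                   (fg.electrode_sign != 0).T.astype(float),
                   levels=[0.5], colors="w", linewidths=0.5)
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    ax.figure.colorbar(im, ax=ax, label="|E_rms| (V/m)")
    return ax


def plot_snapshot(positions, grid, ax=None, view: str = "top", **scatter_kw):
    """Scatter one configuration snapshot (positions in node units)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pos = np.asarray(positions)
    x = grid.x[pos[:, 0]] * 1e6
    y = grid.y[pos[:, 1]] * 1e6
    z = grid.z[pos[:, 2]] * 1e6
    if view == "top":
        ax.scatter(x, y, s=scatter_kw.pop("s", 4), **scatter_kw)
        ax.set_xlabel("x (um)")
        ax.set_ylabel("y (um)")
    else:
        ax.scatter(x, z, s=scatter_kw.pop("s", 4), **scatter_kw)
        ax.set_xlabel("x (um)")
        ax.set_ylabel("z (um)")
    ax.set_aspect("equal")
    return ax
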