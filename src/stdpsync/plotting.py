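"""Optional contour rendering of weight-change surfaces (requires matplotlib).

Isolated from all numeric code: nothing else in the package imports this
module, and no numeric output depends on plotting.
"""

from __future__ import annotations

import numpy as np

from .surfaces import WeightChangeSurface


def plot_surface(surface: WeightChangeSurface, ax=None, levels: int = 21, **contour_kw):
    """Filled contour plot of a surface (rows on the y axis, columns on x).

    Masked cells are left blank.  Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt  # deferred: plotting is optional

    if ax is None:
        _, ax = plt.subplots()
    values = np.ma.masked_invalid(surface.values)
    if surface.mask is not None:
        values = np.ma.masked_where(surface.mask, values)
    cs = ax.contourf(surface.axis2, surface.axis1, values, levels=levels, **contour_kw)
    ax.figure.colorbar(cs, ax=ax, label=surface.meta.get("quantity", "value"))
    ax.set_xlabel(surface.axis2_name)
    ax.set_ylabel(surface.axis1_name)
    if "preset" in surface.meta:
        ax.set_title(str(surface.meta["preset"]))
    return ax
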