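"""Small plotting helpers (line + shaded HPDI band + naive points).

Matplotlib is imported lazily so the core library has no hard plotting
dependency.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plot_occupancy", "plot_wpi"]


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots(figsize=(5, 3.2))
    return ax


def plot_occupancy(years, point, lo, hi, naive=None, ax=None, title=None):
    """Modeled occupancy trajectory with its HPDI band and naive points."""
    ax = _ax(ax)
    years = np.asarray(years)
    ax.fill_between(years, lo, hi, alpha=0.3, color="grey", lw=0)
    ax.plot(years, point, color="k")
    if naive is not None:
        ax.plot(years, naive, "o", color="k", ms=4)
    ax.set_xlabel("year")
    ax.set_ylabel("occupancy")
    ax.set_ylim(0, 1)
    if title:
        ax.set_title(title)
    return ax


def plot_wpi(series, ax=None, title=None):
    """WPI trajectory with its HPDI band and the no-change reference line."""
    ax = _ax(ax)
    ax.fill_between(series.years, series.hpdi_lo, series.hpdi_hi,
                    alpha=0.3, color="grey", lw=0)
    ax.plot(series.years, series.point, color="k")
    ax.axhline(1.0, color="grey", ls=":")
    ax.set_xlabel("year")
    ax.set_ylabel("WPI")
    if title:
        ax.set_title(title)
    return ax
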