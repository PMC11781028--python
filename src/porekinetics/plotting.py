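"""Minimal QC plotting helpers (decoration only, untested)."""

from __future__ import annotations

import numpy as np


def ridgeline(pdfs, boundaries=None, ax=None, spacing=1.2, color="C0"):
    """Stacked per-minute amplitude PDFs, earliest minute at the top."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 6))
    pdfs = [p for p in pdfs if p is not None]
    scale = max(float(np.max(p.density)) for p in pdfs)
    for row, pdf in enumerate(pdfs):
        y0 = -row * spacing
        ax.fill_between(pdf.grid, y0, y0 + pdf.density / scale,
                        color=color, alpha=0.6, lw=0.5, edgecolor="k")
    if boundaries is not None:
        ax.axvline(boundaries.lower, color="crimson", ls="--", lw=1)
        ax.axvline(boundaries.upper, color="crimson", ls="--", lw=1)
    ax.set_xlabel("peak amplitude (nA)")
    ax.set_yticks([-(i) * spacing for i in range(len(pdfs))],
                  [str(p.minute) for p in pdfs])
    ax.set_ylabel("minute")
    return ax


def probability_scatter(series, fit=None, ax=None):
    """Probability-vs-time scatter with the optional initial-velocity line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(series.minutes, series.probability, "o", ms=4)
    if fit is not None:
        t = np.linspace(*fit.window, 50)
        ax.plot(t, fit.intercept + fit.slope * t, "-", color="crimson",
                label=f"m = {fit.slope:+.2f} %/min")
        ax.legend(frameon=False)
    ax.set_xlabel("digestion time (min)")
    ax.set_ylabel("P(reactant) (%)")
    ax.set_ylim(0, 100)
    return ax
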