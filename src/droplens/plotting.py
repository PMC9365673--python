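"""Minimal plotting helpers for the standard figures of this analysis:
enrichment bars against the area-fraction null, registered z-density
profiles, and diameter histograms with their fitted count models."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np


def plot_enrichment(summary, ax=None):
    """Bar chart of inside-ring fractions with the area-null dashed line.

    ``summary`` is the tidy frame from :func:`enrichment_summary`.
    """
    import matplotlib.pyplot as plt
    ax = ax or plt.gca()
    ax.bar(summary["species"], summary["fraction"], color="#7494c4")
    ax.axhline(summary["null"].iloc[0], ls="--", color="k", lw=1,
               label="ring area fraction")
    ax.set_ylabel("fraction of lipids inside the ring")
    ax.legend(frameon=False)
    return ax


def plot_density_profiles(profiles: Sequence, ax=None):
    """Overlay registered z-density profiles (max-normalised)."""
    import matplotlib.pyplot as plt
    ax = ax or plt.gca()
    for p in profiles:
        ax.plot(p.bin_centers, p.density, label=p.label)
    ax.axvline(0.0, color="k", lw=0.5)
    ax.set_xlabel("z (nm, bilayer-registered)")
    ax.set_ylabel("normalised density")
    ax.legend(frameon=False)
    return ax


def plot_diameter_fit(hist, pair=None, ax=None):
    """Diameter histogram with the fitted Gaussian/log-normal curves."""
    import matplotlib.pyplot as plt
    from .stats import gaussian_counts, lognormal_counts
    ax = ax or plt.gca()
    ax.bar(hist.centers, hist.counts, width=hist.bin_width * 0.9,
           color="0.8", label="data")
    if pair is not None:
        x = np.linspace(hist.centers.min(), hist.centers.max(), 300)
        g = pair.gaussian.params
        ax.plot(x, gaussian_counts(x, g["amplitude"], g["location"],
                                   g["scale"]),
                label=f"gaussian (w={pair.gaussian.akaike_weight:.2f})")
        ln = pair.lognormal.params
        ax.plot(x, lognormal_counts(x, ln["amplitude"], ln["location"],
                                    ln["scale"]),
                label=f"log-normal (w={pair.lognormal.akaike_weight:.2f})")
    ax.set_xlabel("diameter (µm)")
    ax.set_ylabel("count")
    ax.legend(frameon=False)
    return ax
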