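"""Minimal matplotlib views of the analysis outputs.

Everything here consumes the result objects from :mod:`fragribo.fragments`
and :mod:`fragribo.footprints`; nothing is computed in this module.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .fragments import LengthDistribution, MotifProfile
from .footprints import MetageneProfile

_BASE_COLORS = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}


def plot_length_density(dist: LengthDistribution, ax=None, normalized=True):
    """Histogram of (normalized) read lengths."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    if normalized:
        edges, counts = dist.norm_edges, dist.norm_counts
        ax.set_xlabel("read length / annotated transcript length")
    else:
        edges, counts = dist.raw_edges, dist.raw_counts
        ax.set_xlabel("aligned read length (nt)")
    ax.stairs(counts, edges, fill=True, alpha=0.6)
    ax.set_ylabel("reads")
    return ax


def plot_motif_logo(profile: MotifProfile, ax=None):
    """Stacked-bar sequence logo: per-position base frequency scaled by IC."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 2.5))
    freqs = profile.counts.div(profile.n_windows)
    for i, offset in enumerate(profile.offsets):
        bottom = 0.0
        ic = profile.ic_bits.loc[offset]
        for base in sorted("ACGT", key=lambda b: freqs.loc[offset, b]):
            height = freqs.loc[offset, base] * ic
            if height > 0:
                label = "U" if base == "T" else base
                ax.bar(offset, height, bottom=bottom,
                       color=_BASE_COLORS[base], width=0.85)
                if height > 0.12:
                    ax.text(offset, bottom + height / 2, label,
                            ha="center", va="center", fontsize=7, color="white")
                bottom += height
    ax.set_xlabel("offset from mapped 5' end (nt)")
    ax.set_ylabel("information (bits)")
    ax.set_ylim(0, 2)
    return ax


def plot_metagene(profile: MetageneProfile, ax=None, label=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(profile.offsets, profile.value, drawstyle="steps-mid", label=label)
    ax.axvline(0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("offset (nt)")
    ax.set_ylabel("normalized mean occupancy")
    if label:
        ax.legend(frameon=False)
    return ax


def plot_footprint_lengths(fractions, ax=None):
    """Bar plot of the normalized 15-34 nt footprint length distribution."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    ax.bar(np.asarray(fractions.index), fractions.values, width=0.8)
    ax.set_xlabel("footprint length (nt, pre-trim)")
    ax.set_ylabel("fraction of reads")
    return ax
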