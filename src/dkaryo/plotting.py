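"""Optional per-sample diagnostic plots (requires matplotlib)."""

from __future__ import annotations

import numpy as np


def plot_genome_z(zrow, binset, path, z_min: float = 2.5):
    """Genome-wide bin Z-score scatter; bins beyond +/- z_min in red."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    z = np.asarray(zrow.z)
    x = np.arange(len(z))
    fig, ax = plt.subplots(figsize=(14, 3))
    hot = np.abs(z) >= z_min
    ax.scatter(x[~hot], z[~hot], s=2, c="steelblue")
    ax.scatter(x[hot], z[hot], s=4, c="crimson")
    for chrom in binset.chroms:
        lo, _ = binset.chrom_slice(chrom)
        ax.axvline(lo, color="0.85", lw=0.5, zorder=0)
    ax.axhline(z_min, color="0.6", ls="--", lw=0.5)
    ax.axhline(-z_min, color="0.6", ls="--", lw=0.5)
    ax.set_xlabel("bin")
    ax.set_ylabel("Z")
    ax.set_title(zrow.sample_id)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_log2_profile(profile, path):
    """1 Mb log2-ratio scatter with per-chromosome medians."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = profile.grid
    x = np.arange(len(grid))
    fig, ax = plt.subplots(figsize=(14, 3))
    ax.scatter(x, profile.m, s=3, c="steelblue")
    for i, chrom in enumerate(grid.chroms):
        idx = np.where(grid.chrom_of == i)[0]
        med = profile.per_chrom_median.get(chrom)
        if med is not None and len(idx):
            ax.plot([idx[0], idx[-1]], [med, med], c="crimson", lw=1.5)
        ax.axvline(idx[0], color="0.85", lw=0.5, zorder=0)
    ax.set_xlabel("1 Mb bin")
    ax.set_ylabel("log2 ratio")
    ax.set_title(profile.sample_id)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
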