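"""Optional diagnostic plots (never inputs to any computation)."""

from __future__ import annotations

import numpy as np


def plot_attractor_overlay(cycles, attractor, path, axes=(0, 2)):
    """Overlay normalized stride cycles (grey) and their attractor (black).

    ``axes`` picks the two acceleration components to plot against each
    other (default medio-lateral vs vertical), showing the limit-cycle
    loops around the mean cycle.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    i, j = axes
    fig, ax = plt.subplots(figsize=(5, 5))
    for c in cycles:
        ax.plot(c.samples[:, i], c.samples[:, j], color="0.7", lw=0.5)
    ax.plot(attractor.mean_cycle[:, i], attractor.mean_cycle[:, j],
            color="black", lw=1.5)
    ax.set_xlabel(f"a[{i}] (m/s$^2$)")
    ax.set_ylabel(f"a[{j}] (m/s$^2$)")
    ax.set_title(f"{attractor.foot} foot, condition {attractor.condition}, "
                 f"n={attractor.n_strides}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_reference(reference, individual_attractors, path, axes=(0, 2)):
    """Group reference attractor (black) over individual attractors (grey)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    i, j = axes
    fig, ax = plt.subplots(figsize=(5, 5))
    for att in individual_attractors:
        ax.plot(att.mean_cycle[:, i], att.mean_cycle[:, j], color="0.7", lw=0.7)
    ax.plot(reference.mean_cycle[:, i], reference.mean_cycle[:, j],
            color="black", lw=1.8)
    ax.set_xlabel(f"a[{i}] (m/s$^2$)")
    ax.set_ylabel(f"a[{j}] (m/s$^2$)")
    ax.set_title(f"reference attractor, {reference.foot} foot, "
                 f"N={reference.n_subjects}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
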