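"""Thin plotting helpers for score-space inspection.

Matplotlib is an optional dependency; import errors surface only when a plot
is actually requested.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plot_scores", "plot_cumulative_variance"]


def plot_scores(scores: np.ndarray, labels, dims=(0, 1), ax=None):
    """Scatter the first two score dimensions, one marker style per class."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    scores = np.asarray(scores)
    labels = np.asarray(labels, dtype=object)
    for lab in dict.fromkeys(labels):
        sel = labels == lab
        ax.scatter(scores[sel, dims[0]], scores[sel, dims[1]], label=str(lab))
    ax.set_xlabel(f"component {dims[0] + 1}")
    ax.set_ylabel(f"component {dims[1] + 1}")
    ax.legend()
    return ax


def plot_cumulative_variance(model, ax=None):
    """Step plot of retained variance fraction versus component count."""
    import matplotlib.pyplot as plt

    from .eigenodour import cumulative_variance

    if ax is None:
        _, ax = plt.subplots()
    cum = cumulative_variance(model)
    ax.step(np.arange(1, cum.size + 1), 100.0 * cum, where="post")
    ax.set_xlabel("components")
    ax.set_ylabel("cumulative variance (%)")
    ax.set_ylim(0, 105)
    return ax
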