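"""Basic raster (actogram-style) and phase plots."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def actogram(scores: np.ndarray, days=None, ax=None, threshold: float | None = None):
    """Raster of the day-by-24 score matrix: days as rows, hours as columns.

    An optional binarisation threshold overlays the sleep classification as
    hatching.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(8, max(2, 0.12 * scores.shape[0])))
    im = ax.imshow(scores, aspect="auto", cmap="viridis",
                   interpolation="nearest")
    ax.set_xlabel("hour (UTC)")
    ax.set_ylabel("day")
    if days is not None and len(days) > 1:
        ax.set_yticks([0, len(days) - 1])
        ax.set_yticklabels([str(days[0]), str(days[-1])])
    if threshold is not None:
        asleep = scores < threshold
        ys, xs = np.nonzero(asleep)
        ax.scatter(xs, ys, marker=".", s=2, c="white", alpha=0.5)
    plt.colorbar(im, ax=ax, label="typing-activity score")
    return ax


def phase_plot(phases, ax=None):
    """Daily phase (hours, UTC) over time with resultant length as alpha."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    sub = phases[phases["defined"]]
    ax.scatter(sub.index, sub["phase_hours"], s=12,
               c=sub["resultant_length"], cmap="cividis")
    ax.set_ylim(0, 24)
    ax.set_xlabel("day index")
    ax.set_ylabel("phase (h, UTC)")
    ax.set_yticks([0, 6, 12, 18, 24])
    return ax
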