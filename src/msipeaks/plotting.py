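"""Simple per-marker histogram + peak plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .histograms import LengthHistogram
from .peaks import PeakSet, pad_and_densify, smooth


def plot_marker_histogram(
    histogram: LengthHistogram,
    peak_set: PeakSet | None = None,
    path: str | Path | None = None,
    ax=None,
):
    """Bar plot of the length histogram with detected peaks marked.

    When the peak set was produced with smoothing, the smoothed series is
    overlaid so the detected positions line up with what was thresholded.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    lengths = sorted(histogram.counts)
    ax.bar(lengths, [histogram.counts[k] for k in lengths], color="0.7", width=0.8)
    if peak_set is not None and peak_set.hyperparameters.smoothing:
        series, offset = pad_and_densify(histogram)
        if offset is not None:
            smoothed = smooth(series)
            x = [i + offset - 1 for i in range(len(smoothed))]
            ax.plot(x, smoothed, color="C0", lw=1, label="smoothed")
    if peak_set is not None:
        for peak in peak_set.peaks:
            ax.axvline(peak.position, color="C3", ls="--", lw=1)
            ax.annotate(
                f"{peak.position}",
                (peak.position, peak.height),
                textcoords="offset points",
                xytext=(0, 4),
                ha="center",
                fontsize=8,
                color="C3",
            )
    ax.set_xlabel("repeat length (bp)")
    ax.set_ylabel("reads")
    title = f"{histogram.sample_id} {histogram.tissue} {histogram.marker_name}"
    ax.set_title(title, fontsize=9)
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
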