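"""Peak discovery in repeat-length histograms.

The pipeline is: densify the histogram over a contiguous length range with
a zero bin added at each end (so boundary alleles can still be local
maxima), optionally smooth with a centered window-3 moving average,
detect strict local maxima (an "eminent number in the middle of three"),
annotate each candidate with a relative height, and retain candidates at
or above the threshold ``r_h``.

Relative height is a peak's (possibly smoothed) height divided by a depth
summary.  Two denominator conventions are provided:

``mean_nonzero_bins`` (default)
    height / mean height over the nonzero bins of the current series.
    Relative heights may exceed 1, which is what makes threshold grids
    extending to 3.0 meaningful; a threshold of 0.2 then reads as "20% of
    average depth".

``peak_sum``
    height / sum of all candidate-peak heights, so relative heights of
    the candidates add to 1 and the threshold only makes sense below 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Tolerance for the rh >= R_h comparison, so grid values sitting exactly
#: on a relative height do not flap on float rounding.
RH_TOLERANCE = 1e-9

DENOMINATOR_MODES = ("mean_nonzero_bins", "peak_sum")


@dataclass(frozen=True)
class Hyperparameters:
    """Peak-discovery settings: smoothing on/off and the height threshold."""

    smoothing: bool = True
    r_h: float = 0.2
    denominator_mode: str = "mean_nonzero_bins"

    def __post_init__(self) -> None:
        if not self.r_h > 0:
            raise ValueError(f"r_h must be > 0, got {self.r_h}")
        if self.denominator_mode not in DENOMINATOR_MODES:
            raise ValueError(
                f"denominator_mode must be one of {DENOMINATOR_MODES}, "
                f"got {self.denominator_mode!r}"
            )


@dataclass(frozen=True)
class Peak:
    position: int  # repeat length, bp
    height: float  # possibly smoothed count
    relative_height: float


@dataclass
class PeakSet:
    """Filtered peaks for one sample x tissue x marker, ascending position."""

    sample_id: str
    tissue: str
    marker_name: str
    peaks: list[Peak] = field(default_factory=list)
    hyperparameters: Hyperparameters = field(default_factory=Hyperparameters)
    total_reads: int = 0

    def __post_init__(self) -> None:
        positions = [p.position for p in self.peaks]
        if positions != sorted(set(positions)):
            raise ValueError("peak positions must be strictly increasing")

    @property
    def positions(self) -> list[int]:
        return [p.position for p in self.peaks]

    def __len__(self) -> int:
        return len(self.peaks)


def pad_and_densify(histogram) -> tuple[np.ndarray, int | None]:
    """Dense height series over [min length - 1, max length + 1].

    Unobserved lengths inside the range become zero bins; one zero bin is
    appended on each side.  Returns ``(series, offset)`` where ``offset``
    is the repeat length corresponding to index 0; an empty histogram
    yields an empty series with offset ``None``.
    """
    counts = histogram.counts if hasattr(histogram, "counts") else dict(histogram)
    if not counts:
        return np.zeros(0, dtype=float), None
    lo, hi = min(counts), max(counts)
    offset = lo - 1
    series = np.zeros(hi - lo + 3, dtype=float)
    for length, count in counts.items():
        series[length - offset] = count
    return series, offset


def smooth(series: np.ndarray) -> np.ndarray:
    """Window-3 moving average, h'_n = (h_{n-1} + h_n + h_{n+1}) / 3.

    The output range is the input range extended by one bin on each side;
    positions outside the input are true zeros.  Total mass is conserved
    (each input value contributes one third to three output bins).
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        return series.copy()
    return np.convolve(series, np.ones(3)) / 3.0


def detect_candidate_peaks(series: Sequence[float]) -> list[tuple[int, float]]:
    """Strict local maxima of a zero-padded series, as (index, height).

    A maximal plateau of equal values counts as a single candidate at its
    leftmost index when both plateau flanks are strictly lower.  Values
    outside the series are treated as zero.
    """
    arr = np.asarray(series, dtype=float)
    n = arr.size
    candidates: list[tuple[int, float]] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and arr[j + 1] == arr[i]:
            j += 1
        left = arr[i - 1] if i > 0 else 0.0
        right = arr[j + 1] if j + 1 < n else 0.0
        if arr[i] > left and arr[i] > right:
            candidates.append((i, float(arr[i])))
        i = j + 1
    return candidates


def relative_heights(
    candidates: Sequence[tuple[int, float]],
    series: Sequence[float],
    denominator_mode: str = "mean_nonzero_bins",
) -> list[tuple[int, float, float]]:
    """Annotate candidates with rh = height / depth summary.

    See the module docstring for the two denominator conventions.  An
    all-zero series has no depth to normalize by and raises ValueError.
    """
    arr = np.asarray(series, dtype=float)
    nonzero = arr[arr > 0]
    if nonzero.size == 0:
        raise ValueError("cannot compute relative heights: series has no depth")
    if denominator_mode == "mean_nonzero_bins":
        denom = float(nonzero.mean())
    elif denominator_mode == "peak_sum":
        denom = float(sum(h for _, h in candidates))
        if denom == 0.0:
            return []
    else:
        raise ValueError(f"unknown denominator_mode {denominator_mode!r}")
    return [(idx, h, h / denom) for idx, h in candidates]


def find_peaks(histogram, hyperparameters: Hyperparameters | None = None) -> PeakSet:
    """Full peak discovery for one histogram.

    Thin wrapper over :class:`msipeaks.estimators.PeakCaller`, which owns
    the densify -> (smooth) -> detect -> threshold composition.
    """
    from .estimators import PeakCaller

    hp = hyperparameters or Hyperparameters()
    caller = PeakCaller(
        smoothing=hp.smoothing,
        r_h=hp.r_h,
        denominator_mode=hp.denominator_mode,
    ).fit()
    return caller.call_histogram(histogram)


def peak_set_rows(peak_set: PeakSet) -> list[dict]:
    """Flatten a PeakSet into TSV/JSON-ready row dicts."""
    return [
        {
            "sample_id": peak_set.sample_id,
            "tissue": peak_set.tissue,
            "marker": peak_set.marker_name,
            "position": p.position,
            "height": p.height,
            "relative_height": p.relative_height,
        }
        for p in peak_set.peaks
    ]
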