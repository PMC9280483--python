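"""Hyperparameter tuning against PCR fragment-analysis peak counts.

PCR capillary electrophoresis gives a gold-standard number of allele
peaks per sample and marker.  The ``diff`` loss is the sum over samples
and markers of absolute differences between sequencing-derived and PCR
peak counts, divided by the number of samples (not by samples x markers),
i.e. the average per-sample total peak-count discrepancy.  The grid
search evaluates every (smoothing, threshold) combination on the
training histograms and returns the minimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .histograms import LengthHistogram, TISSUES
from .peaks import Hyperparameters

#: The default threshold grid: 0.1, 0.2, ..., 3.0.
DEFAULT_THRESHOLDS = tuple(k / 10 for k in range(1, 31))
DEFAULT_SMOOTHING_OPTIONS = (True, False)

#: (sample_id, tissue, marker_name) -> peak count
CountKey = tuple[str, str, str]


@dataclass
class PCRTruth:
    """Gold-standard peak counts keyed by (sample_id, tissue, marker)."""

    entries: dict[CountKey, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, count in self.entries.items():
            if int(count) < 1:
                raise ValueError(f"PCR peak count must be >= 1, got {count} at {key}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PCRTruth":
        """Load a truth TSV with columns sample_id, tissue, marker, peak_count."""
        table = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        required = ("sample_id", "tissue", "marker", "peak_count")
        missing = [c for c in required if c not in table.columns]
        if missing:
            raise ValueError(f"PCR truth {path}: missing columns {missing}")
        if table.empty:
            raise ValueError(f"PCR truth {path}: no entries")
        entries: dict[CountKey, int] = {}
        for _, row in table.iterrows():
            key = (str(row["sample_id"]), str(row["tissue"]), str(row["marker"]))
            if key[1] not in TISSUES:
                raise ValueError(f"PCR truth {path}: bad tissue {key[1]!r}")
            if key in entries:
                raise ValueError(f"PCR truth {path}: duplicate entry {key}")
            entries[key] = int(row["peak_count"])
        return cls(entries)

    def restrict_tissues(self, tissues: Sequence[str]) -> "PCRTruth":
        keep = set(tissues)
        return PCRTruth({k: v for k, v in self.entries.items() if k[1] in keep})

    @property
    def n_samples(self) -> int:
        """Number of distinct (sample_id, tissue) units — the S of the loss."""
        return len({(s, t) for s, t, _ in self.entries})


@dataclass
class TuningResult:
    grid: list[tuple[Hyperparameters, float]]
    best: Hyperparameters
    best_diff: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"smoothing": hp.smoothing, "threshold": hp.r_h, "diff": diff}
                for hp, diff in self.grid
            ]
        )


def diff_loss(
    ngs_counts: Mapping[CountKey, int], pcr: PCRTruth
) -> float:
    """Average per-sample total absolute peak-count difference.

    ``diff = sum_i sum_t |P_NGS(i,t) - P_PCR(i,t)| / S`` with S the number
    of (sample, tissue) units in the truth table.  Every truth key must be
    present in ``ngs_counts``.
    """
    missing = [k for k in pcr.entries if k not in ngs_counts]
    if missing:
        raise KeyError(f"NGS peak counts missing for truth entries: {missing}")
    if not pcr.entries:
        raise ValueError("empty PCR truth")
    total = sum(abs(int(ngs_counts[k]) - v) for k, v in pcr.entries.items())
    return total / pcr.n_samples


def peak_counts(
    histograms: Iterable[LengthHistogram], hyperparameters: Hyperparameters
) -> dict[CountKey, int]:
    """Detected peak count per histogram under one hyperparameter setting."""
    from .peaks import find_peaks

    return {h.key: len(find_peaks(h, hyperparameters)) for h in histograms}


def grid_search(
    histograms: Sequence[LengthHistogram],
    pcr: PCRTruth,
    thresholds: Sequence[float] | None = None,
    smoothing_options: Sequence[bool] | None = None,
    denominator_mode: str = "mean_nonzero_bins",
    tissues: Sequence[str] | None = None,
) -> TuningResult:
    """Exhaustive search over smoothing x threshold minimizing diff_loss.

    Ties break toward smoothing on, then the lowest threshold (a lower
    threshold keeps smaller alleles visible, i.e. more sensitivity).
    Thin wrapper over :meth:`msipeaks.estimators.MSIClassifier.fit`.
    """
    from .estimators import MSIClassifier

    clf = MSIClassifier(
        denominator_mode=denominator_mode,
        thresholds=thresholds,
        smoothing_options=smoothing_options,
        tissues=tissues,
    )
    clf.fit(list(histograms), pcr)
    return clf.tuning_result_
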