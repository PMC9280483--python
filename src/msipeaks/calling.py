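"""Stable/unstable marker calls and patient MSI classification.

A marker is unstable when tumor and normal peak counts differ, or when the
counts are equal but pairing the peaks in ascending-position order leaves
a maximum absolute position gap of at least 2 repeat units.  A patient
with two or more unstable markers is MSI-H, otherwise MSI-L (MSS and
MSI-L are merged into a single low-instability label; ``n_unstable`` is
reported so the Bethesda MSS/MSI-L split can be recovered).

Markers where either sample has fewer than ``min_reads`` anchor-matched
reads are called uninformative and excluded from the unstable count — a
depth guard this package adds on top of the decision rules, since calling
on near-empty histograms is unsafe.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .histograms import LengthHistogram
from .markers import Marker
from .peaks import Hyperparameters, PeakSet

UNSTABLE_GAP = 2  # minimum tumor/normal peak-position gap calling instability
MSIH_MIN_UNSTABLE = 2  # minimum unstable markers for an MSI-H verdict
DEFAULT_MIN_READS = 20

STATUS_STABLE = "stable"
STATUS_UNSTABLE = "unstable"
STATUS_UNINFORMATIVE = "uninformative"


class UncallableError(ValueError):
    """No informative marker: the patient cannot be classified."""


@dataclass
class MarkerCall:
    marker_name: str
    status: str
    tumor_peak_count: int
    normal_peak_count: int
    max_position_gap: int | None
    reason: str

    def to_dict(self) -> dict:
        return {
            "marker": self.marker_name,
            "status": self.status,
            "tumor_peak_count": self.tumor_peak_count,
            "normal_peak_count": self.normal_peak_count,
            "max_position_gap": self.max_position_gap,
            "reason": self.reason,
        }


@dataclass
class PatientCall:
    sample_id: str
    status: str  # "MSI-H" or "MSI-L"
    n_unstable: int
    n_evaluated: int
    marker_calls: list[MarkerCall] = field(default_factory=list)

    @property
    def unstable_markers(self) -> list[str]:
        return [c.marker_name for c in self.marker_calls if c.status == STATUS_UNSTABLE]

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "status": self.status,
            "n_unstable": self.n_unstable,
            "n_evaluated": self.n_evaluated,
            "unstable_markers": self.unstable_markers,
            "marker_calls": [c.to_dict() for c in self.marker_calls],
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def summary_line(self) -> str:
        """One-line TSV: sample_id, status, n_unstable, unstable markers."""
        names = ",".join(self.unstable_markers) or "."
        return f"{self.sample_id}\t{self.status}\t{self.n_unstable}\t{names}"


def compare_marker(
    tumor: PeakSet, normal: PeakSet, min_reads: int = DEFAULT_MIN_READS
) -> MarkerCall:
    """Call one marker stable/unstable from tumor and normal peak sets.

    The call is symmetric under swapping tumor and normal; only the
    ``reason`` text records direction.
    """
    if tumor.marker_name != normal.marker_name:
        raise ValueError(
            f"marker mismatch: tumor={tumor.marker_name!r} "
            f"normal={normal.marker_name!r}"
        )
    name = tumor.marker_name
    nt, nn = len(tumor), len(normal)
    if tumor.total_reads < min_reads or normal.total_reads < min_reads:
        return MarkerCall(
            name,
            STATUS_UNINFORMATIVE,
            nt,
            nn,
            None,
            f"insufficient depth (tumor={tumor.total_reads}, "
            f"normal={normal.total_reads}, min_reads={min_reads})",
        )
    if nt != nn:
        return MarkerCall(
            name,
            STATUS_UNSTABLE,
            nt,
            nn,
            None,
            f"peak counts differ (tumor={nt}, normal={nn})",
        )
    gaps = [abs(t - n) for t, n in zip(tumor.positions, normal.positions)]
    max_gap = max(gaps, default=0)
    if max_gap >= UNSTABLE_GAP:
        return MarkerCall(
            name,
            STATUS_UNSTABLE,
            nt,
            nn,
            max_gap,
            f"equal peak counts but position gap {max_gap} >= {UNSTABLE_GAP}",
        )
    return MarkerCall(
        name, STATUS_STABLE, nt, nn, max_gap, f"max position gap {max_gap}"
    )


def classify_patient(
    marker_calls: Sequence[MarkerCall], sample_id: str
) -> PatientCall:
    """MSI-H iff at least ``MSIH_MIN_UNSTABLE`` informative markers are unstable."""
    informative = [c for c in marker_calls if c.status != STATUS_UNINFORMATIVE]
    if not informative:
        raise UncallableError(
            f"sample {sample_id!r}: no informative marker; cannot classify"
        )
    n_unstable = sum(1 for c in informative if c.status == STATUS_UNSTABLE)
    status = "MSI-H" if n_unstable >= MSIH_MIN_UNSTABLE else "MSI-L"
    return PatientCall(
        sample_id=sample_id,
        status=status,
        n_unstable=n_unstable,
        n_evaluated=len(informative),
        marker_calls=list(marker_calls),
    )


def call_histogram_pair(
    tumor_histograms: Sequence[LengthHistogram],
    normal_histograms: Sequence[LengthHistogram],
    hyperparameters: Hyperparameters | None = None,
    min_reads: int = DEFAULT_MIN_READS,
    sample_id: str | None = None,
) -> PatientCall:
    """Classify a patient from per-marker tumor and normal histograms.

    Thin wrapper over :meth:`msipeaks.estimators.MSIClassifier.call_pair`.
    """
    from .estimators import MSIClassifier

    hp = hyperparameters or Hyperparameters()
    clf = MSIClassifier(
        smoothing=hp.smoothing,
        r_h=hp.r_h,
        denominator_mode=hp.denominator_mode,
        min_reads=min_reads,
    )
    return clf.call_pair(tumor_histograms, normal_histograms, sample_id=sample_id)


def call_sample_pair(
    tumor_bam: str | Path,
    normal_bam: str | Path,
    markers: Sequence[Marker],
    hyperparameters: Hyperparameters | None = None,
    min_reads: int = DEFAULT_MIN_READS,
    min_mapq: int = 1,
    drop_duplicates: bool = True,
    sample_id: str | None = None,
) -> PatientCall:
    """End-to-end: extract both BAMs, discover peaks, call the patient."""
    from .extraction import extract_length_histograms

    sid = sample_id or Path(tumor_bam).stem
    tumor_hists = extract_length_histograms(
        tumor_bam, markers, sid, "tumor", min_mapq, drop_duplicates
    )
    normal_hists = extract_length_histograms(
        normal_bam, markers, sid, "normal", min_mapq, drop_duplicates
    )
    return call_histogram_pair(
        tumor_hists, normal_hists, hyperparameters, min_reads, sample_id=sid
    )
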