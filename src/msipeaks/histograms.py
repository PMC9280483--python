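"""Repeat-length histograms ("depth files") and their tab-separated layout.

A :class:`LengthHistogram` maps repeat length (bp) to the number of
anchor-matched reads observing that length, for one sample x tissue x
marker.  The on-disk depth file is a TSV with columns ``sample_id``,
``tissue``, ``marker``, ``repeat_length``, ``count`` — one row per
observed length — preceded by a ``#`` header line carrying the tool
version.  Histograms with no observed lengths serialize to zero rows and
are therefore absent after a round trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

TISSUES = ("tumor", "normal")


class DepthFileError(ValueError):
    """Raised on malformed depth-file content; carries the line number."""


@dataclass
class LengthHistogram:
    sample_id: str
    tissue: str
    marker_name: str
    counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(f"tissue must be one of {TISSUES}, got {self.tissue!r}")
        for length, count in self.counts.items():
            if int(length) < 1:
                raise ValueError(f"repeat length must be >= 1, got {length}")
            if int(count) < 0:
                raise ValueError(f"count must be >= 0, got {count} at length {length}")
        self.counts = {int(k): int(v) for k, v in sorted(self.counts.items())}

    @property
    def total(self) -> int:
        """Number of anchor-matched reads behind this histogram."""
        return sum(self.counts.values())

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.sample_id, self.tissue, self.marker_name)


_COLUMNS = ("sample_id", "tissue", "marker", "repeat_length", "count")


def write_depth_file(histograms: Iterable[LengthHistogram], path: str | Path) -> None:
    """Write histograms as a depth TSV; record order is preserved."""
    from . import __version__

    with open(path, "w") as fh:
        fh.write(f"# msipeaks depth file v{__version__}\n")
        fh.write("\t".join(_COLUMNS) + "\n")
        for hist in histograms:
            for length in sorted(hist.counts):
                count = hist.counts[length]
                if count == 0:
                    continue
                fh.write(
                    f"{hist.sample_id}\t{hist.tissue}\t{hist.marker_name}"
                    f"\t{length}\t{count}\n"
                )


def read_depth_file(path: str | Path) -> list[LengthHistogram]:
    """Read a depth TSV back into histograms.

    Consecutive rows sharing (sample_id, tissue, marker) form one record;
    record order follows the file.  Malformed lines raise
    :class:`DepthFileError` naming the offending line number.
    """
    records: list[LengthHistogram] = []
    current: LengthHistogram | None = None
    header_seen = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(_COLUMNS):
                raise DepthFileError(
                    f"{path}:{lineno}: expected {len(_COLUMNS)} fields, "
                    f"got {len(fields)}"
                )
            if not header_seen:
                if tuple(fields) != _COLUMNS:
                    raise DepthFileError(
                        f"{path}:{lineno}: bad header {fields!r}"
                    )
                header_seen = True
                continue
            sample_id, tissue, marker, length_s, count_s = fields
            try:
                length, count = int(length_s), int(count_s)
            except ValueError as exc:
                raise DepthFileError(f"{path}:{lineno}: {exc}") from None
            key = (sample_id, tissue, marker)
            if current is None or current.key != key:
                try:
                    current = LengthHistogram(sample_id, tissue, marker, {})
                except ValueError as exc:
                    raise DepthFileError(f"{path}:{lineno}: {exc}") from None
                records.append(current)
            if length < 1 or count < 0:
                raise DepthFileError(
                    f"{path}:{lineno}: invalid length/count {length}/{count}"
                )
            current.counts[length] = current.counts.get(length, 0) + count
    if not header_seen:
        raise DepthFileError(f"{path}: missing column header line")
    for rec in records:  # restore sorted-key invariant after in-place fill
        rec.counts = dict(sorted(rec.counts.items()))
    return records
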