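"""Anchor matching in reads and histogram extraction from BAM files.

Repeat length is measured directly on each read's stored sequence: the 5'
flank, a maximal run of the repeat base, then the 3' flank starting at the
first non-repeat-base position.  The forward anchor is tried first, then
the complementary-reverse anchor; a read contributes at most one count.
Because the run is read off the read itself, insertions and deletions in
the repeat tract are captured by the run length — no realignment is done.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .histograms import LengthHistogram
from .markers import Marker


def fetch_window(marker: Marker) -> tuple[str, int, int]:
    """1-based inclusive marker coordinates -> 0-based half-open window.

    This is the single place where the coordinate convention changes.
    """
    return marker.chrom, marker.start - 1, marker.end


def match_anchor(read_sequence: str, marker: Marker) -> int | None:
    """Repeat-run length between the marker's flanks, or None if unmatched.

    The forward anchor has priority; the CR anchor is tried only when the
    forward anchor is absent.  The leftmost occurrence wins.  An ``N``
    inside the candidate run breaks the run (N never equals the repeat
    base), giving conservative length calls.
    """
    m = marker.forward_regex.search(read_sequence)
    if m is None:
        m = marker.cr_regex.search(read_sequence)
    if m is None:
        return None
    return m.end(1) - m.start(1)


def extract_length_histograms(
    alignments: str | Path,
    markers: Sequence[Marker],
    sample_id: str,
    tissue: str,
    min_mapq: int = 1,
    drop_duplicates: bool = True,
) -> list[LengthHistogram]:
    """Build one repeat-length histogram per marker from a BAM file.

    Reads overlapping each marker window are fetched; unmapped, secondary
    and supplementary alignments are skipped, as are reads below
    ``min_mapq`` and (when ``drop_duplicates``) duplicate-flagged reads.
    Each surviving read is anchor-matched on its stored sequence and
    contributes at most one count.
    """
    path = Path(alignments)
    if not path.exists():
        raise FileNotFoundError(f"BAM file not found: {path}")
    with pysam.AlignmentFile(str(path), "rb") as bam:
        try:
            bam.check_index()
        except (ValueError, AttributeError) as exc:
            raise FileNotFoundError(
                f"BAM index missing for {path}; run samtools index"
            ) from exc
        references = set(bam.references)
        histograms = []
        for marker in markers:
            if marker.chrom not in references:
                raise ValueError(
                    f"marker {marker.name!r}: chromosome {marker.chrom!r} "
                    "absent from BAM header"
                )
            chrom, start0, end = fetch_window(marker)
            counts: Counter[int] = Counter()
            for read in bam.fetch(chrom, start0, end):
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    continue
                if read.mapping_quality < min_mapq:
                    continue
                if drop_duplicates and read.is_duplicate:
                    continue
                seq = read.query_sequence
                if not seq:
                    continue
                length = match_anchor(seq.upper(), marker)
                if length is not None:
                    counts[length] += 1
            histograms.append(
                LengthHistogram(sample_id, tissue, marker.name, dict(counts))
            )
    return histograms
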