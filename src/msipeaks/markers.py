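"""Microsatellite marker definitions and the default six-marker panel.

A marker is a mononucleotide repeat tract located by two short unique
anchor sequences: the 5' flank immediately preceding the run and the 3'
flank immediately following it.  Anchors are written in the compact
notation ``FLANK5(B+)FLANK3`` (e.g. ``TTTGA(T+)GAGAA`` for a poly-T run),
and every marker also carries the complementary-reverse (CR) anchor so
that reads sequenced from either strand can be matched.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import cached_property
from importlib import resources
from pathlib import Path

import pandas as pd

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_ANCHOR_RE = re.compile(r"^([ACGT]+)\(([ACGT])\+\)([ACGT]+)$")
_POSITION_RE = re.compile(r"^([\w.]+):(\d+)-(\d+)$")

REQUIRED_COLUMNS = ("name", "position", "anchor", "anchor_cr", "repeat_length")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class MarkerTableError(ValueError):
    """Raised when a marker table row cannot be parsed or validated."""


@dataclass(frozen=True)
class Marker:
    """One microsatellite locus with its anchor decomposition.

    Coordinates are 1-based inclusive, as conventionally printed for
    genomic intervals; conversion to 0-based half-open fetch windows
    happens in exactly one place (:func:`msipeaks.extraction.fetch_window`).
    """

    name: str
    chrom: str
    start: int
    end: int
    flank5: str
    repeat_base: str
    flank3: str
    flank5_rc: str
    repeat_base_rc: str
    flank3_rc: str
    ref_repeat_length: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise MarkerTableError(
                f"marker {self.name!r}: start {self.start} > end {self.end}"
            )
        if not self.flank5 or not self.flank3:
            raise MarkerTableError(f"marker {self.name!r}: empty anchor flank")
        if self.repeat_base not in "ACGT":
            raise MarkerTableError(
                f"marker {self.name!r}: repeat base {self.repeat_base!r} not in ACGT"
            )
        if self.ref_repeat_length < 1:
            raise MarkerTableError(
                f"marker {self.name!r}: non-positive reference repeat length"
            )
        # CR anchor must be the reverse complement of the forward anchor,
        # decomposed the same way.
        expected = (
            reverse_complement(self.flank3),
            self.flank5_rc,
            self.repeat_base.translate(_COMPLEMENT),
            self.repeat_base_rc,
            reverse_complement(self.flank5),
            self.flank3_rc,
        )
        if expected[::2] != expected[1::2]:
            raise MarkerTableError(
                f"marker {self.name!r}: CR anchor "
                f"{self.flank5_rc}({self.repeat_base_rc}+){self.flank3_rc} is not the "
                f"reverse complement of {self.flank5}({self.repeat_base}+){self.flank3}"
            )

    @cached_property
    def forward_regex(self) -> re.Pattern[str]:
        # Greedy run plus a lookahead: the 3' flank must start at the first
        # non-repeat-base position after the run (maximal-run semantics).
        return re.compile(
            f"{self.flank5}({self.repeat_base}+)(?!{self.repeat_base}){self.flank3}"
        )

    @cached_property
    def cr_regex(self) -> re.Pattern[str]:
        return re.compile(
            f"{self.flank5_rc}({self.repeat_base_rc}+)"
            f"(?!{self.repeat_base_rc}){self.flank3_rc}"
        )

    @property
    def anchor(self) -> str:
        return f"{self.flank5}({self.repeat_base}+){self.flank3}"

    @property
    def anchor_cr(self) -> str:
        return f"{self.flank5_rc}({self.repeat_base_rc}+){self.flank3_rc}"


def parse_anchor(anchor: str, row_name: str = "?") -> tuple[str, str, str]:
    """Decompose ``FLANK5(B+)FLANK3`` into (flank5, repeat_base, flank3)."""
    m = _ANCHOR_RE.match(anchor.strip().upper())
    if m is None:
        raise MarkerTableError(
            f"row {row_name!r}: malformed anchor notation {anchor!r} "
            "(expected FLANK5(B+)FLANK3)"
        )
    return m.group(1), m.group(2), m.group(3)


def _parse_position(position: str, row_name: str) -> tuple[str, int, int]:
    m = _POSITION_RE.match(position.strip())
    if m is None:
        raise MarkerTableError(
            f"row {row_name!r}: malformed position {position!r} "
            "(expected chrom:start-end)"
        )
    return m.group(1), int(m.group(2)), int(m.group(3))


def load_marker_table(path: str | Path) -> list[Marker]:
    """Load a tab-separated marker table.

    Required columns: ``name``, ``position`` (``chrom:start-end``, 1-based
    inclusive), ``anchor`` and ``anchor_cr`` in ``FLANK5(B+)FLANK3``
    notation, and ``repeat_length`` (reference repeat length in bp).
    The complementary-reverse anchor is checked for consistency with the
    forward anchor at load time.
    """
    table = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise MarkerTableError(f"marker table {path}: missing columns {missing}")
    markers = []
    for _, row in table.iterrows():
        name = str(row["name"]).strip()
        chrom, start, end = _parse_position(str(row["position"]), name)
        f5, base, f3 = parse_anchor(str(row["anchor"]), name)
        f5_rc, base_rc, f3_rc = parse_anchor(str(row["anchor_cr"]), name)
        markers.append(
            Marker(
                name=name,
                chrom=chrom,
                start=start,
                end=end,
                flank5=f5,
                repeat_base=base,
                flank3=f3,
                flank5_rc=f5_rc,
                repeat_base_rc=base_rc,
                flank3_rc=f3_rc,
                ref_repeat_length=int(row["repeat_length"]),
            )
        )
    names = [m.name for m in markers]
    if len(set(names)) != len(names):
        raise MarkerTableError(f"marker table {path}: duplicate marker names")
    return markers


def default_panel() -> list[Marker]:
    """The bundled six-marker mononucleotide panel."""
    with resources.as_file(
        resources.files("msipeaks.data").joinpath("markers.tsv")
    ) as path:
        return load_marker_table(path)
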