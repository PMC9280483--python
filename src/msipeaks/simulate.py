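"""Synthetic repeat-length data with known truth, for testing end to end.

The generator emulates what PCR stutter and sequencing noise do to a
mononucleotide-repeat length distribution: reads from an allele of modal
length L mostly report L, with a geometrically decaying tail of shorter
lengths (polymerase slippage removes repeat units far more often than it
adds them), a much smaller upward tail, and a low rate of stray uniform
lengths from mismapped or chimeric reads.  Defaults are chosen to look
like a well-covered amplicon panel: ~200x depth per marker, a dominant
one-unit-down stutter shoulder of ~15% of reads, and isolated 1-read
noise bins that raw local-maximum detection would report as peaks —
which is exactly what smoothing plus the relative-height threshold must
remove.

It also writes tiny sorted+indexed BAM fixtures whose reads embed
``flank5 + repeat_base*k + flank3`` at the marker locus, so the real
extraction path can be exercised without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pysam

from .extraction import match_anchor
from .histograms import LengthHistogram
from .markers import Marker, default_panel

DEFAULT_DEPTH = 500.0
DEFAULT_STUTTER_DOWN = 0.10
DEFAULT_STUTTER_UP = 0.04
DEFAULT_NOISE_RATE = 0.002
#: Tumor-only shorter alleles are planted this many repeat units below the
#: reference allele (PCR fragment analysis resolves shifts of this size).
NOVEL_ALLELE_SHIFTS = (5, 6, 7)
#: Fraction of tumor depth carried by a planted novel allele.
NOVEL_ALLELE_FRACTION = 0.6


@dataclass(frozen=True)
class AlleleModel:
    """One allele's read-length distribution.

    ``stutter_down_rate`` / ``stutter_up_rate`` are geometric decay
    parameters: the number of repeat units lost (gained) per read is
    geometric with P(k) = (1 - rate) * rate**k, so rate 0 means no
    stutter and 0.15 puts ~15% of reads one or more units short.
    ``noise_rate`` is the per-read probability of a stray uniform length.
    """

    modal_length: int
    depth: float = DEFAULT_DEPTH
    stutter_down_rate: float = DEFAULT_STUTTER_DOWN
    stutter_up_rate: float = DEFAULT_STUTTER_UP
    noise_rate: float = DEFAULT_NOISE_RATE

    def __post_init__(self) -> None:
        if not self.depth > 0:
            raise ValueError("depth must be > 0")
        for rate in (self.stutter_down_rate, self.stutter_up_rate, self.noise_rate):
            if not 0.0 <= rate < 1.0:
                raise ValueError("rates must lie in [0, 1)")
        if self.modal_length < 1:
            raise ValueError("modal_length must be >= 1")


def _geometric_offsets(rng: np.random.Generator, rate: float, n: int) -> np.ndarray:
    if rate == 0.0 or n == 0:
        return np.zeros(n, dtype=int)
    # numpy's geometric counts trials (>=1); offsets are failures (>=0)
    return rng.geometric(1.0 - rate, size=n) - 1


def simulate_histogram(
    alleles: Sequence[AlleleModel],
    seed: int | np.random.Generator,
    sample_id: str = "sim",
    tissue: str = "tumor",
    marker_name: str = "simulated",
) -> LengthHistogram:
    """Draw a stutter-broadened length histogram for the given alleles.

    Read count per allele is Poisson around its depth; each read's length
    is the modal length shifted down/up by independent geometric stutter
    offsets, or (with ``noise_rate``) replaced by a stray length uniform
    over the alleles' neighborhood.  Deterministic for a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    modal = [a.modal_length for a in alleles]
    lo = max(1, min(modal, default=1) - 15)
    hi = max(modal, default=1) + 15
    counts: dict[int, int] = {}
    for allele in alleles:
        n = int(rng.poisson(allele.depth))
        if n == 0:
            continue
        down = _geometric_offsets(rng, allele.stutter_down_rate, n)
        up = _geometric_offsets(rng, allele.stutter_up_rate, n)
        lengths = np.maximum(allele.modal_length - down + up, 1)
        stray = rng.random(n) < allele.noise_rate
        lengths[stray] = rng.integers(lo, hi + 1, size=int(stray.sum()))
        for length in lengths:
            counts[int(length)] = counts.get(int(length), 0) + 1
    return LengthHistogram(sample_id, tissue, marker_name, counts)


@dataclass
class CohortPair:
    sample_id: str
    tumor: list[LengthHistogram]
    normal: list[LengthHistogram]
    true_status: str  # "MSI-H" or "MSI-L"
    unstable_markers: list[str] = field(default_factory=list)


def simulate_cohort(
    n_pairs: int,
    fraction_msih: float,
    seed: int,
    markers: Sequence[Marker] | None = None,
    depth: float = DEFAULT_DEPTH,
    stutter_down_rate: float = DEFAULT_STUTTER_DOWN,
    stutter_up_rate: float = DEFAULT_STUTTER_UP,
    noise_rate: float = DEFAULT_NOISE_RATE,
) -> list[CohortPair]:
    """Tumor/normal histogram pairs with planted MSI truth.

    Every normal sample carries one allele per marker at the reference
    repeat length.  MSI-H tumors additionally gain a novel shorter
    allele at 2-4 randomly chosen markers; MSI-L tumors at most one.
    The number of MSI-H pairs is round(n_pairs * fraction_msih).
    """
    if not 0.0 <= fraction_msih <= 1.0:
        raise ValueError("fraction_msih must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    panel = list(markers) if markers is not None else default_panel()
    n_msih = int(round(n_pairs * fraction_msih))
    labels = np.array(["MSI-H"] * n_msih + ["MSI-L"] * (n_pairs - n_msih))
    rng.shuffle(labels)

    def allele(modal: int, d: float) -> AlleleModel:
        return AlleleModel(
            modal_length=modal,
            depth=d,
            stutter_down_rate=stutter_down_rate,
            stutter_up_rate=stutter_up_rate,
            noise_rate=noise_rate,
        )

    pairs: list[CohortPair] = []
    for i, label in enumerate(labels):
        sid = f"sim{i:03d}"
        n_hit = (
            int(rng.integers(2, 5)) if label == "MSI-H" else int(rng.integers(0, 2))
        )
        hit_idx = rng.choice(len(panel), size=n_hit, replace=False)
        hit_names = {panel[j].name for j in hit_idx}
        tumor, normal = [], []
        for marker in panel:
            ref_allele = allele(marker.ref_repeat_length, depth)
            normal.append(
                simulate_histogram(
                    [ref_allele], rng, sid, "normal", marker.name
                )
            )
            tumor_alleles = [ref_allele]
            if marker.name in hit_names:
                shift = int(rng.choice(NOVEL_ALLELE_SHIFTS))
                tumor_alleles.append(
                    allele(
                        max(1, marker.ref_repeat_length - shift),
                        depth * NOVEL_ALLELE_FRACTION,
                    )
                )
            tumor.append(
                simulate_histogram(tumor_alleles, rng, sid, "tumor", marker.name)
            )
        pairs.append(
            CohortPair(
                sample_id=sid,
                tumor=tumor,
                normal=normal,
                true_status=str(label),
                unstable_markers=sorted(hit_names),
            )
        )
    return pairs


# -- BAM fixtures -----------------------------------------------------

_PAD = 20  # bases of random padding flanking the anchor in fixture reads


def write_fixture_bam(
    plans: Mapping[str, Mapping[int, int]],
    markers: Sequence[Marker],
    path: str | Path,
    duplicate_plans: Mapping[str, Mapping[int, int]] | None = None,
    seed: int = 0,
) -> Path:
    """Write a sorted, indexed BAM realizing per-marker length plans.

    ``plans[marker_name][k] = n`` places n reads, each embedding
    ``flank5 + repeat_base*k + flank3`` inside random padding, at the
    marker's locus; extraction on the output reproduces the plan
    exactly.  ``duplicate_plans`` adds duplicate-flagged reads the same
    way.  Reference names and a minimal coordinate-sorted header are
    synthesized from the marker table.
    """
    path = Path(path)
    panel = {m.name: m for m in markers}
    unknown = set(plans) - set(panel)
    if unknown:
        raise ValueError(f"plans reference unknown markers {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    chroms: dict[str, int] = {}
    for m in markers:
        chroms[m.chrom] = max(chroms.get(m.chrom, 0), m.end + 1000)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": chrom, "LN": length} for chrom, length in chroms.items()],
    }
    tid = {chrom: i for i, chrom in enumerate(chroms)}

    def build_sequence(marker: Marker, k: int) -> str:
        core = marker.flank5 + marker.repeat_base * k + marker.flank3
        bases = np.array(list("ACGT"))
        for _ in range(20):
            pad5 = "".join(rng.choice(bases, size=_PAD))
            pad3 = "".join(rng.choice(bases, size=_PAD))
            seq = pad5 + core + pad3
            if match_anchor(seq, marker) == k:
                return seq
        raise RuntimeError(
            f"could not embed a clean anchor for {marker.name} run {k}"
        )  # pragma: no cover - padding collision 20 times in a row

    reads = []
    all_plans = [(plans, 0)]
    if duplicate_plans:
        all_plans.append((duplicate_plans, pysam.FDUP))
    for plan, extra_flag in all_plans:
        for marker_name, lengths in plan.items():
            marker = panel[marker_name]
            for k, n in lengths.items():
                for i in range(int(n)):
                    seq = build_sequence(marker, int(k))
                    a = pysam.AlignedSegment()
                    a.query_name = f"{marker_name}:{k}:{extra_flag}:{i}"
                    a.query_sequence = seq
                    a.flag = extra_flag
                    a.reference_id = tid[marker.chrom]
                    a.reference_start = marker.start - 1
                    a.mapping_quality = 60
                    a.cigar = [(0, len(seq))]
                    a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
                    reads.append(a)
    reads.sort(key=lambda r: (r.reference_id, r.reference_start, r.query_name))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for read in reads:
            bam.write(read)
    pysam.index(str(path))
    return path


def write_cohort_bams(
    pair: CohortPair,
    markers: Sequence[Marker],
    directory: str | Path,
    seed: int = 0,
) -> tuple[Path, Path]:
    """Materialize one cohort pair as tumor/normal fixture BAMs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tumor_plan = {h.marker_name: h.counts for h in pair.tumor}
    normal_plan = {h.marker_name: h.counts for h in pair.normal}
    tumor_path = write_fixture_bam(
        tumor_plan, markers, directory / f"{pair.sample_id}.tumor.bam", seed=seed
    )
    normal_path = write_fixture_bam(
        normal_plan, markers, directory / f"{pair.sample_id}.normal.bam", seed=seed + 1
    )
    return tumor_path, normal_path
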