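# Methods

## Problem and model

Microsatellite instability is read out per marker as a change in the
set of allele lengths between tumor and matched normal tissue. PCR
fragment analysis counts electropherogram peaks; this package emulates
that count on sequencing data. The unit of evidence is the repeat-length
histogram: for each marker, every read whose sequence contains the
marker's anchor (5' flank, maximal repeat-base run, 3' flank — or the
reverse complement of the whole pattern) contributes its run length.
Measuring the run on the read itself means replication slippage events
(the biological signal) and PCR/sequencing stutter (the noise) both
appear directly as histogram bins; no realignment or reference
comparison is involved. Because tumor and normal are measured on the
same platform, platform-specific length offsets cancel in the
comparison.

Anchor matching is greedy with a hard boundary: the 3' flank must start
at the first non-repeat-base position after the run. The forward anchor
has priority over the complementary-reverse one, the leftmost occurrence
in a read wins, and a read is never counted twice. An `N` inside the run
breaks it (conservative: such reads simply fail to match rather than
yield a shortened length).

## Peak discovery

The histogram is densified over `[min observed − 1, max observed + 1]`
with zero bins at both ends so boundary alleles can be detected. The
pipeline order is fixed as **smooth → detect → filter**: both noise-
reduction strategies act on the same final series, and the threshold is
applied to peaks that exist on that series.

* **Smoothing** is a centered window-3 moving average; the output range
  extends one bin each side and total mass is conserved exactly in
  rational arithmetic (each value is an integer sum of three neighbors
  divided by 3 — tests verify conservation by reconstructing the
  integer numerators, since float thirds do not sum exactly).
* **Detection** keeps strict local maxima; a plateau of equal values is
  one candidate at its leftmost bin. A consequence worth knowing: an
  isolated spike at length L smooths to an exact three-bin plateau, so
  with smoothing on its reported position is L − 1. Tumor and normal are
  affected identically, so marker comparison is unaffected; with any
  stutter asymmetry present the tie disappears and the peak sits at the
  modal length.
* **Relative height** defaults to `h / mean(nonzero bins of the current
  series)` — "fraction of average depth" — because that keeps the
  threshold grid up to 3.0 meaningful. The alternative `peak_sum`
  normalization (divide by the sum of candidate heights, so values cap
  at 1) is provided for comparison. When smoothing is on, both the
  heights and the denominator come from the smoothed series.
* The retention comparison `rh ≥ R_h` uses a 1e−9 tolerance so grid
  values landing exactly on a relative height do not flap on float
  rounding.

## Calling rules and their constants

Unstable marker: different tumor/normal peak counts, or equal counts
with a max ascending-order pairing gap ≥ 2 repeat units. Ascending-
order pairing is the simplest order-preserving matching; the gap is
absolute, so the call is symmetric under tumor/normal swap. Patient:
≥ 2 unstable markers → MSI-H, else MSI-L (exactly one unstable marker
is MSI-L, consistent with merging MSS and MSI-L into one low label).
A zero-informative-marker panel raises an explicit error rather than
silently reporting MSI-L.

`min_reads` (default 20 matched reads per marker per sample) is this
package's depth guard: below it a marker is `uninformative` and leaves
both the unstable count and the evaluated count. It is configurable and
clearly labeled in reports.

## Tuning

`diff = Σ_i Σ_t |P_NGS − P_PCR| / S` with `S` the number of distinct
(sample, tissue) units in the truth table; by default both tissues
contribute as separate units, and a tumor-only switch is exposed since
truth tables are sometimes typed on tumor material only. The grid is
{smoothing on, off} × {0.1 … 3.0 in steps of 0.1} (60 combinations);
ties break toward lower diff, then smoothing on, then the lowest
threshold, generalizing the preference for sensitivity that motivates
operating at 0.2. Defaults ship as smoothing on, R_h = 0.2.

## Synthetic data

The generator emulates stutter-broadened allele distributions. Per
allele: read count ~ Poisson(depth); each read's length is the modal
length minus a geometric down-shift (parameter `stutter_down_rate`,
P(k) = (1−d)·d^k) plus an independent geometric up-shift
(`stutter_up_rate`), with a `noise_rate` chance of a stray uniform
length. Defaults: depth 500 (typical amplicon-panel coverage at MSI
loci), down 0.10 per unit, up 0.04 per unit, noise 0.002.

The up rate is deliberately above the square of the down rate: under
window-3 smoothing the detected position prefers the modal length L
over L−1 exactly when h(L+1) > h(L−2), i.e. when up > down², and the
depth gives that comparison a comfortable Poisson margin. A nonzero up
rate is realistic for homopolymer over-calls on semiconductor
sequencers. The stray-read rate produces isolated 1-read bins — raw
local-maximum detection would call them peaks, which is precisely the
noise the smoothing + threshold combination must remove, and what the
noise-suppression tests assert.

Cohorts plant truth: normals carry the reference allele per marker;
MSI-H tumors gain a novel shorter allele (5–7 units down, 60% of the
reference depth) at 2–4 random markers, MSI-L tumors at ≤ 1. What the
simulation does **not** model: base-calling errors and quality scores,
read pairing, tumor purity/subclonality below the fixed 60% allele
fraction, mapping artifacts, and anchor-sequence mutations. Passing
end-to-end tests therefore demonstrates the decision logic and its
noise robustness at plausible signal-to-noise, not performance on real
cohorts.

Fixture BAMs embed `flank5 + base×k + flank3` in random padding at the
marker's real hg19 coordinates, with a synthesized header; padding is
re-drawn if it ever creates a spurious anchor match, so extraction
reproduces a length plan exactly.

## Problem sizes and numerical choices

Test and acceptance workloads are sized for quick desk runs: 1,000
random series for the detection oracle, 1,000/100 random histograms for
conservation/monotonicity, a 60-pair cohort (~720 histograms) for
end-to-end recovery; the whole suite runs in well under a minute.
Degenerate inputs are defined, not errors: empty histograms give empty
peak sets; an all-zero series cannot be normalized and raises; depth
files serialize only observed lengths, so an empty histogram
round-trips to absence.

## Known limitations

Peak prominence and minimum-distance criteria are not implemented; the
plateau convention makes the smoothed lone-spike position sit one unit
low (see above); the six-marker panel is mononucleotide-only; no
continuous MSI score is produced — the output is the binary
MSI-H/MSI-L verdict plus per-marker evidence.
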