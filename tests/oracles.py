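"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they validate: anchor matching is
done by character scanning instead of regex, and peak detection by
exhaustive plateau enumeration instead of the single-pass scanner.
"""

from __future__ import annotations


def scan_anchor_oracle(seq: str, flank5: str, base: str, flank3: str) -> int | None:
    """Leftmost flank5 + maximal base-run + flank3 via substring scanning."""
    start = 0
    while True:
        i = seq.find(flank5, start)
        if i < 0:
            return None
        j = i + len(flank5)
        k = j
        while k < len(seq) and seq[k] == base:
            k += 1
        run = k - j
        if run > 0 and seq[k : k + len(flank3)] == flank3:
            return run
        start = i + 1


def match_anchor_oracle(seq: str, marker) -> int | None:
    fwd = scan_anchor_oracle(seq, marker.flank5, marker.repeat_base, marker.flank3)
    if fwd is not None:
        return fwd
    return scan_anchor_oracle(
        seq, marker.flank5_rc, marker.repeat_base_rc, marker.flank3_rc
    )


def detect_peaks_oracle(series) -> list[tuple[int, float]]:
    """Every leftmost-of-plateau strict local maximum, by full enumeration."""
    vals = list(series)
    n = len(vals)

    def at(i):
        return vals[i] if 0 <= i < n else 0.0

    out = []
    for i in range(n):
        if at(i - 1) == vals[i]:  # not the leftmost of its plateau
            continue
        j = i
        while j + 1 < n and vals[j + 1] == vals[i]:
            j += 1
        if vals[i] > at(i - 1) and vals[i] > at(j + 1):
            out.append((i, float(vals[i])))
    return out


def diff_loss_oracle(ngs_counts, truth_entries) -> float:
    """Naive double loop over samples and markers."""
    units = sorted({(s, t) for s, t, _ in truth_entries})
    total = 0
    for s, t in units:
        for key, pcr in truth_entries.items():
            if (key[0], key[1]) == (s, t):
                total += abs(ngs_counts[key] - pcr)
    return total / len(units)
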