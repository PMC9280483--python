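# msipeaks

Tumor/normal microsatellite-instability (MSI) calling from sequencing
data, by making read-count histograms of repeat-tract lengths behave
like PCR fragment-analysis electropherograms.

## Who this is for

MSI status (MSI-H vs MSI-L/MSS) guides immunotherapy decisions and
Lynch-syndrome screening. The clinical gold standard counts allele
peaks per microsatellite marker in PCR capillary electrophoresis.
`msipeaks` reproduces that readout directly from aligned reads: if a
panel is already being sequenced, MSI status comes for free, with no
separate PCR assay. It targets bioinformaticians running tumor/matched-
normal panels and anyone who needs a small, transparent, tunable MSI
caller whose two hyperparameters can be re-fit to a new platform from a
handful of PCR-typed samples.

## The method

For each of six mononucleotide markers (BAT-25, BAT-26, MONO-27, NR-21,
NR-24, NR-27) a read is matched against the marker's **anchor**
`FLANK5(B+)FLANK3` — the unique 5' flank, a maximal run of the repeat
base B, and the 3' flank beginning at the first non-B position — or its
reverse complement. The run length of each matched read populates a
histogram h(length) per sample and marker (the *depth file*).

Peak discovery on the zero-padded histogram:

1. optional smoothing, `h'_n = (h_{n-1} + h_n + h_{n+1}) / 3`;
2. candidate peaks = strict local maxima (a tie plateau counts once, at
   its leftmost bin);
3. relative height `rh_n = h_n / d̄`, where `d̄` is by default the mean
   over nonzero bins of the current series ("average depth"; a
   normalization by the sum of peak heights is also available);
4. keep peaks with `rh_n ≥ R_h`.

Marker comparison: a marker is **unstable** if tumor and normal peak
counts differ, or if the counts are equal but pairing peaks in
ascending order leaves a position gap ≥ 2 repeat units. A patient with
**≥ 2 unstable markers is MSI-H**, otherwise MSI-L. Markers with fewer
than `min_reads` (default 20) matched reads in either sample are
uninformative and excluded.

Tuning: given PCR truth counts `P_PCR(i,t)` the loss

    diff = Σ_i Σ_t | P_NGS(i,t) − P_PCR(i,t) | / S

(S = number of samples) is minimized by exhaustive grid search over
smoothing × `R_h ∈ {0.1, 0.2, …, 3.0}`, ties broken toward smoothing
and the lowest threshold (sensitivity). The shipped defaults are
smoothing on, `R_h = 0.2`.

The library is also exposed as sklearn-style estimators: `PeakCaller`
(histograms → peak sets, a transformer) and `MSIClassifier`
(`fit` = grid search against PCR truth, `predict` = MSI-H/MSI-L per
tumor/normal pair).

## Worked example

Simulate a small cohort with known truth, then call it:

```bash
$ msipeaks simulate --n-pairs 4 --fraction-msih 0.5 --seed 42 -o demo
wrote 4 pairs to demo
$ cat demo/manifest.tsv
sample_id	true_status	unstable_markers	depth_file
sim000	MSI-L	.	sim000.depth.tsv
sim001	MSI-L	Bat26	sim001.depth.tsv
sim002	MSI-H	Bat26,Mono27,NR21,NR24	sim002.depth.tsv
sim003	MSI-H	Mono27,NR21,NR27	sim003.depth.tsv
$ msipeaks call --tumor demo/sim002.depth.tsv --normal demo/sim002.depth.tsv \
      --sample-id sim002 -o sim002.json
sim002	MSI-H	4	Bat26,Mono27,NR21,NR24
```

The summary line is `sample_id  status  n_unstable  unstable_markers`:
sim002 is called MSI-H because four markers are unstable (≥ 2). The
JSON report carries the per-marker evidence, e.g. for BAT-26:

```json
{
  "marker": "Bat26",
  "status": "unstable",
  "tumor_peak_count": 2,
  "normal_peak_count": 1,
  "reason": "peak counts differ (tumor=2, normal=1)"
}
```

— the tumor gained a second, shorter allele at this marker while the
normal kept one, the signature of an unstable microsatellite.
`msipeaks extract` produces depth files from indexed BAMs, and
`msipeaks call` accepts BAMs directly in place of depth files.
`msipeaks tune --depth train.tsv --truth pcr.tsv` prints the best
(smoothing, threshold) combination and its `diff`.

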