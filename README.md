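# ribostall

Codon-level analysis of ribosome profiling data: A-site-assigned codon
occupancy, metagene detection of ribosome queuing upstream of stalled codons,
and translation-efficiency analysis binned by codon content — plus a
synthetic footprint generator so that every stage can be exercised and
verified on a laptop, with no sequencing data required.

## The problem

Ribosome profiling sequences the ~17–30 nt mRNA fragments protected by
translating ribosomes (ribosome-protected fragments, RPFs). Because each
fragment pins a ribosome to a position, RPF density read at codon resolution
reports how long ribosomes dwell on each codon. Under some stresses a single
codon decodes slowly — for example the lone tryptophan codon UGG when charged
tRNA-Trp runs low under oxidative stress — and stalled ribosomes cause
trailing ribosomes to queue behind them at one-footprint (≈10 codon) spacing.
This package implements the three statistics that make that biology visible:

**Relative codon occupancy.** For each coding sequence, over the eligible
region (codons strictly after position 90, stop codon excluded, so the
initiation ramp does not bias the statistic):

- *f(c)* — fraction of the gene's eligible RPFs with their A-site on codon
  identity *c*;
- *a(c)* — fraction of the gene's eligible codon positions with identity *c*;
- *o(c) = f(c)/a(c)* — normalized occupancy, with Σ_c a(c)·o(c) = 1 exactly.

Occupancies are averaged unweighted over genes into a 61-codon profile;
*o(c) ≈ 1* means average dwell, *o(c) > 1* slow decoding. Footprint 5′ ends
are mapped to the decoded codon with a per-read-length A-site offset table
(default 15 nt for 27–31-nt reads; calibratable from start-codon metagenes).

**Metagene queuing profiles.** Mean normalized RPF density at codon offsets
±30 around every occurrence of a target codon (each window normalized by its
mean, so the profile of a flat library sits at 1). A stalled codon shows a
peak at offset 0; queued ribosomes appear as secondary peaks one and two
ribosome widths upstream (−10 and −20 codons for 30-nt footprints). A peak
caller (strict local maxima ≥ 1.5× the window median) and a stack-count
summary turn the profile into "how many ribosomes deep is the queue".

**Translation efficiency by codon content.** log2 TE = log2((RPF + ½)/(mRNA
+ ½)) per gene, median-centred; TE changes between conditions are binned into
11 groups by target-codon content (one zero-content group plus ten
equal-size ascending groups) and tested for a content trend with a
permutation Spearman statistic. Gene-list overlaps are scored with the
one-sided hypergeometric (Fisher) test.

The synthetic generator produces transcriptomes, dwell-weighted footprints
(with configurable stalling and an explicit queued-footprint emission rule)
and matched RNA-seq counts in the same FASTA/BED/TSV dialects the readers
accept, so closed-form expectations exist for every downstream statistic.

## Worked example

```python
import ribostall as rs

transcripts = rs.generate_transcriptome(n_genes=200, length_range_codons=(250, 600), seed=0)
stress = rs.make_scenario("h2o2", n_footprints=1_000_000, seed=1)
sim = rs.simulate_footprints(transcripts, stress)
tracks = rs.build_count_tracks(sim, rs.default_offsets(), transcripts).tracks

profile = rs.average_occupancy(rs.occupancy_by_gene(tracks, transcripts))
print(f"o(UGG) = {profile.occupancy('TGG'):.2f}")

metagene = rs.metagene_profile(tracks, transcripts, "TGG")
peaks = rs.detect_peaks(metagene, min_ratio=1.5)
called = sorted(p.position for p in peaks if p.passes_threshold)
print(f"called peaks at codon offsets {called}")
print(f"stacked ribosomes: {rs.queue_summary(peaks)}")
```

prints

```
o(UGG) = 6.74
called peaks at codon offsets [-20, -10, 0]
stacked ribosomes: 3
```

The oxidative-stress scenario multiplies UGG dwell by 8 and emits queued
footprints with probability 0.3 per depth. The measured occupancy (6.74, not
8) is the closed-form mixture expectation: the stall inflates the gene's
total read count, and queued reads land on non-UGG codons, both of which
dilute *o*(UGG). The called peaks at −10 and −20 are the queued ribosomes;
the stack count (stall + two queued = 3) is read off the peak positions.

The same pipeline is available from the shell:

```bash
ribostall simulate --name h2o2 --n-genes 200 --seed 1 --out-dir sim/
ribostall occupancy --bed sim/footprints.bed --fasta sim/cds.fa --out occ.tsv
ribostall metagene  --bed sim/footprints.bed --fasta sim/cds.fa --codon TGG --out-prefix tgg
ribostall te --counts stress.tsv --counts-control control.tsv --fasta sim/cds.fa --out te.tsv
```

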