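# Methods

## Coordinate conventions

Footprint coordinates are 0-based half-open nucleotide positions relative to
the first nucleotide of the start codon (the BED frame); codon indices are
0-based internally. The occupancy cutoff is stated in the 1-based convention
("codons after 90", counting ATG as codon 1), which maps to 0-based indices
≥ 90. The stop codon never carries an A-site assignment and is excluded from
every denominator (occupancy composition, content fractions, metagene
windows). These choices remove off-by-one ambiguity at module boundaries and
are asserted by tests rather than re-derived per module.

## A-site assignment

A footprint's decoded codon is `floor((start + offset(length)) / 3)`. The
default offset is 15 nt for 27–31-nt reads — the canonical 12-nt P-site
offset plus one codon — and the same 15 nt is applied to other lengths
whenever it is geometrically valid (0 < offset < length), otherwise the read
is unassigned. Codon-resolution results are insensitive to ±1 nt within a
codon but not across codons, so the offset table can also be calibrated from
data: initiating ribosomes put their P-site on codon 0, so for each
read-length class the modal 5′-end distance upstream of the ATG gives the
P-site offset and the A-site offset is that distance + 3. Classes with fewer
than 500 reads (configurable) fall back to the default table; tied modes take
the lower offset so calibration is deterministic. Calibration consumes raw
`(transcript, start, length)` records because its informative reads have
negative CDS-relative starts, which the BED reader (whose product feeds
counting, not calibration) rejects as out of bounds.

## Occupancy statistic

Per gene, over eligible positions (1-based codon index > cutoff, stop
excluded): f(c) = eligible reads on identity c / total eligible reads,
a(c) = eligible positions of identity c / total eligible positions,
o(c) = f/a where a > 0 (a codon absent from a gene contributes nothing for
that codon — undefined, not zero, so 0/0 cannot contaminate means). The
identity Σ_c a(c)·o(c) = 1 holds per gene to 1e-9 and is tested. Genes with
fewer than `min_gene_rpf` eligible reads are excluded; the default of 64
bounds per-gene multinomial noise and is configurable. Profiles average o
unweighted across genes — the per-sequence-then-average reading of the
procedure — with read-weighted pooling available behind a flag for
sensitivity analysis, since the averaging scheme is genuinely open.
Condition comparisons report per-codon log2(stress/control) of the mean
occupancies, ranked.

## Metagene profiles and peak calling

For every occurrence of the target codon whose ±`window` (default 30)
codon neighbourhood lies inside the CDS (stop excluded), the count window is
normalized by its own mean and the normalized windows are averaged
position-wise; occurrences with zero window reads are dropped and counted,
and `total = used + boundary_dropped + zero_dropped` is asserted.
Per-occurrence normalization keeps highly expressed genes from dominating
the profile and fixes the flat-profile baseline at exactly 1 (the profile
mean is 1 to 1e-9 by construction). Occurrences of the target codon inside
another occurrence's window remain their own centers; excluding them would
bias against codon-dense genes. The >90-codon occupancy cutoff is not
applied to metagene windows — it belongs to the codon-usage statistic only.

Peaks are strict local maxima within ±2 codons, accepted in descending
height when the density reaches `min_ratio` (default 1.5) times the median
density of the search range, the median being recomputed with ±2 codons
around already-accepted peaks excluded so that a tall stall peak does not
mask its queue. The queue summary counts accepted peaks at offsets
0, −w, −2w, … (±1 codon, w = ribosome width of 10 codons) and reports the
inferred number of stacked ribosomes; a profile with no stall-anchored peak
reports 0.

## Translation efficiency and content bins

log2 TE uses a 0.5 pseudocount so zero-count genes stay finite (they are
flagged); TE changes are stress − control per gene, median-centred
(mean-of-middle-two for even n). Content bins: bin 0 holds exactly the
genes with zero occurrences of the target codon; the remainder are sorted by
(content fraction, gene id) — a deterministic tie-break — and split into ten
contiguous groups whose sizes differ by at most one. The content denominator
is the gene's sense codons (start included, stop excluded), consistent with
the 61-codon occupancy frame. The trend statistic is the Spearman
correlation between bin index 1–10 and bin median TE change, with a
one-sided permutation p-value (999 permutations by default, seeded) obtained
by shuffling gene-to-change assignments within the binned genes. Bin 0 may
be empty — synthetic transcriptomes with ~2% TGG essentially never contain
zero-content genes at 250–600 codons — but any empty bin among 1–10 is an
error. Gene-list overlap significance is the one-sided hypergeometric upper
tail P[overlap ≥ observed], which is the one-sided Fisher exact test for
enrichment; differential-expression and differential-TE testing are out of
scope here, and fold-change thresholds are surfaced only as optional filters
on the ratio tables.

## The synthetic generator

The generator emulates the study conditions, not raw-sequencer realism.
Transcriptomes: each CDS starts with ATG, ends with a uniformly chosen stop,
and draws internal codons i.i.d. from configurable sense-codon weights —
default uniform with TGG re-weighted to a 2% internal fraction, the
tryptophan-content regime of interest. CDS lengths are uniform on a range
(default 250–600 codons) whose minimum must exceed the occupancy cutoff plus
the metagene window so every gene informs every stage.

Footprints are sampled by occupancy, not by a mechanistic TASEP simulation:
the probability of a (gene, codon) placement is proportional to
expression(gene) × dwell(codon identity), restricted to positions where a
maximum-length read fits inside the CDS, which makes a gene's footprint
share proportional to expression × total ribosome transit time. Under
uniform dwell this reduces to expression × length; under a stall it is what
slows stall-codon-rich genes and produces the TE-vs-content trend as an
emergent property rather than a planted label. Keeping the sampler
non-mechanistic keeps every expectation in closed form, so tests can check
the pipeline against arithmetic instead of against another simulator.
Queuing is an explicit emission rule: a footprint whose A-site is the stall
codon seeds a queued footprint k ribosome widths upstream with probability
q^k (k ≤ depth 2; width 10 codons = round(30/3), and the width follows the
footprint length, e.g. 9 codons at 27 nt). Queued placements are exact
multiples of the width by default (an optional jitter is deliberately not a
default: the observed peaks are sharp). Each footprint's 5′ end is placed so
its A-site under the default offset table lands on the intended codon;
placements that would leave the CDS are skipped and counted, and emitted +
skipped totals are conserved and reported.

Footprint lengths are 17–30 nt with a 30-nt mode: a discrete triangular
component on 26–30 peaking at 30 (90% of mass — the canonical protected
fragment) plus a uniform 17–25 tail (10%), matching the gel range of real
libraries without modelling nuclease chemistry. RNA-seq counts are a single
multinomial over genes with probability ∝ expression × length; matched RPF
counts are the per-gene footprint totals.

Scenario presets encode the biology being modelled: `control` (uniform
dwell, no queuing), `h2o2` (oxidative stress: TGG dwell ×8, queue
probability 0.3, depth 2) and `h2o2_trp` (stress with supplemental
tryptophan, which restores charged tRNA-Trp and therefore control dwell —
the rescue condition). The stall magnitude and queue probability are not
measured quantities; they are chosen to reproduce the qualitative
stall-plus-two-queued-peaks pattern at comfortable signal-to-noise and are
fully configurable. Seeding: one master seed per scenario; each stage
(transcriptome, footprints, RNA-seq) uses a deterministically derived child
seed, so stages are individually reproducible.

## What passing tests do and do not show

The generator draws codons i.i.d., gives every gene the same expression by
default, has no UTRs, uORFs, initiation ramps, sequence-dependent nuclease
bias, sequencing error, multimapping or disome (~57 nt) classes. Passing
tests therefore demonstrate that the statistics are implemented correctly
and recover known inputs under the stated sampling model — parameter
recovery (Spearman ≥ 0.9 between injected log-dwell and estimated
log-occupancy), null calibration (uniform dwell → occupancies within 5% of
1 at 10^6 reads, no peak calls), queue geometry (−10/−20 peaks, stack count
3), rescue (UGG excess and queuing abolished), and the planted TE trend.
They do not demonstrate robustness to the biases of real libraries; on real
data the offset calibration, the gene filters and the >90-codon cutoff do
that work, and the occupancy statistic remains a relative, per-condition
measure.

## Problem sizes and numerical choices

Simulation-backed tests and the acceptance script use 200 genes of 250–600
codons and 10^6 footprints — enough that per-codon standard errors are well
inside every asserted band, while a full pipeline run takes seconds. Ties:
calibration modes break to the lower offset, content bins break by gene id,
array splitting puts the larger bins first. Degenerate inputs are values,
not crashes, where the domain has a natural reading (unassigned A-site,
excluded gene, empty peak list); they are errors where silence would corrupt
accounting (empty profiles, empty bins 1–10, all-missing columns).
Floating-point identities (occupancy normalization, metagene window means)
are asserted at 1e-9.
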