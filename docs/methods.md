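# Methods

`syntegrity` audits a genome assembly against an independent assembly of
the same species by (1) finding large synteny breaks between the two,
and (2) testing each break against evidence that is orthogonal to the
assembly process: recombination inferred in a genotyped pedigree,
population linkage disequilibrium, and (externally supplied)
optical-map support. This note records the models, the defaults and why
they are what they are, what the synthetic data do and do not emulate,
and the numerical choices made where the design was open.

## Synteny breaks

Input is a whole-genome alignment (nucmer `show-coords`-style table or
PAF) between assembly A (the one being audited) and assembly B. Blocks
shorter than `min_block` (default 10 kb) are discarded as repeat noise,
and co-linear same-orientation blocks with gaps at most `max_gap`
(default 200 kb) are greedily chained. Defaults were chosen so the
>100 kb reporting floor is insensitive to small repeat-driven blocks;
both are exposed in the API and CLI.

Discordance calling works against a *majority backbone* per
A-chromosome rather than only against immediate flanking chains. The
backbone is the heaviest (a-length-weighted) b-monotone subsequence of
chains — a weighted longest-increasing-subsequence with `max_gap` of
slack — computed per B-chromosome, together with the length-weighted
dominant orientation. Then:

* a chain mapping to a B-chromosome other than the one carrying most of
  the A-chromosome's aligned length is a translocation (Trans);
* a chain off the monotone backbone is a Trans (displaced out of
  order);
* a chain on the backbone but opposing the dominant orientation is an
  inversion (Inv).

The purely local alternative (compare a chain to its two neighbours)
was rejected because it double-reports same-chromosome transpositions
(the large in-order chain between the excision and insertion points is
itself "out of order" relative to its neighbours) and misclassifies
chains at chromosome edges. Only the minority side of a disagreement is
reported, which makes detection symmetric: swapping A and B yields the
same events with coordinates exchanged. A whole-chromosome inversion is
intentionally not callable from that chromosome alone — with no
majority context the data cannot say which assembly is right.

Breakpoints are placed at the midpoint between a flagged chain and its
neighbour (which is also the midpoint of any slight overlap, as nucmer
chains routinely overlap across repeats). Candidates must exceed
`min_size` (default 100 kb) and are reported in size-descending order.
Coordinates are 0-based half-open internally; files use each format's
native convention, and human-readable reports print Mb to 2 decimals.

Point liftover across assemblies goes through the aligned blocks
(`b_start + (pos − a_start)` on + blocks, reflected on − blocks).
Positions in unaligned gaps return an explicit unmapped result, never a
nearest-block guess.

## Pedigree crossover evidence

The design is a sire, two dams, and their offspring (default 9, i.e. 18
scored meioses counting both parental sides). Genotype calls are
filtered hard before anything else: site QUAL > 50, biallelic SNPs
only, per-sample depth ≥ 15 and GQ ≥ 40, allelic balance (minor-read
fraction) > 0.30 for heterozygotes and < 0.07 for homozygotes, and
repeat regions excluded by BED. Informative sites for the paternal
analysis have the sire heterozygous, both dams homozygous and every
offspring called; the maternal analysis reverses the pattern and is run
separately per dam family, since the two dams' phases are independent.
The transmitted allele follows by Mendelian subtraction; impossible
transmissions drop the site (no error correction — the filters aim at
high-confidence sites, and a corrected site would carry exactly the
error the filters exist to exclude).

With the focal parent's phase unknown, complementing any marker row of
the inheritance matrix is free, so the minimum number of crossovers
consistent with the data is Σᵢ min(dᵢ, n − dᵢ) over adjacent marker
pairs, where dᵢ is the Hamming distance between consecutive rows and n
the number of offspring. Events are assigned to the smaller-side
offspring set; the dᵢ = n/2 tie assigns to the set containing the
lowest offspring index and marks the interval ambiguous (totals are
unaffected either way). A switch pair supported by fewer than
`min_support` (default 2) consecutive markers — the signature of a
residual genotyping error or a gene conversion — is removed by flipping
the short interior run; terminal runs are kept because a terminal
switch has no partner and may be a real crossover. Smoothing can only
remove events, never add them.

Events from all meioses are pooled; intervals padded by half the
`merge_window` (default 50 kb, matching the LD proximity scale) are
single-linkage merged, and any group with ≥ `cluster_min` (default 3)
events is flagged. Genuine recombination almost never places three of
eighteen meioses in the same interval, but an assembly misjoin does:
sorting markers by the audited assembly's coordinates makes two
truth-distant loci adjacent, and every meiosis with an odd number of
crossovers between those loci shows an apparent switch exactly there.
A candidate is then labelled start / end / start+end / no by whether a
flag lies within `window` (50 kb) of each breakpoint; disjoint
chromosome name sets between flags and candidates raise an error
(coordinate-system mix-up) instead of silently labelling "no".

The X chromosome is excluded from pedigree analysis (hemizygous
transmission is not modelled).

## LD evidence

The population-scaled recombination rate ρ = 4Nr, estimated from
unrelated individuals (e.g. LDhelmet output), spikes at a misjoin
because LD decays across the false junction as if recombination there
were extreme. The scan reports maximal runs of track intervals with
ρ/bp strictly > 0.2 whose summed ρ strictly exceeds 500 ("region" is
operationalized as a maximal above-threshold run; `merge_gap`, default
0, can bridge track gaps). Candidates are labelled by 50 kb proximity
exactly as for linkage. When the track lives on a third assembly,
breakpoints are lifted first; a breakpoint that fails to lift, or a
candidate whose two lifted breakpoints land on different track
chromosomes (so synteny across the event cannot be verified), is
labelled "unknown". The published ~4% false-discovery rate of this
rule is a reported property of the original data, not recomputed here —
its null construction is unstated.

## Evidence integration

Each candidate gets one record with three labels: linkage, optical-map
(a pass-through flag file — map alignment is out of scope, preserving
the three-source structure without reimplementing it), and LD. A
candidate is corroborated when at least one source is in
{yes, start, end, start+end}; "no" and "unknown" never corroborate,
because with noisy evidence the absence of a signal is inconclusive.
Reports list corroborated candidates first and provisional ones under
an explicit caveat; output is byte-deterministic for fixed input.

The package ships the published 12-row evidence table for the
Panubis1.0 vs Panu_3.0 comparison and the 21-row provisional inversion
catalogue as worked-example inputs; applying the any-source rule to the
former yields 11 of 12 corroborated.

## Synthetic data

The generator builds a truth genome (chromosome name → length) and an
alt assembly derived by planted, non-overlapping inversions and
translocations, represented as an exact piecewise coordinate bijection.
Emitted alignment blocks are what a perfect aligner would produce, so
break detection is tested as the inverse of the planting operation.

Pedigree genotypes are simulated on the *truth* genome: parental
haplotypes are fair-coin alleles per marker, with informativeness
imposed by construction (markers alternate paternal- and
maternal-informative); each meiosis carries Poisson(rate × length)
crossovers at uniform positions. Records are written to VCF sorted by
*alt* coordinates — this single choice reproduces the phenomenon under
study, since truth-space crossovers pile up at misjoin junctions in alt
order. DP is negative-binomial (mean 30, dispersion 20), GQ is high for
correct calls and depressed for planted errors (so the GQ filter
catches most of them and smoothing the rest), AD is binomial around the
called genotype, and QUAL is high. About half the markers survive the
hard filters at these settings, which is intentional: the filters must
do real work in every test.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| marker_density | 1 per 10 kb | dense enough to localise events to tens of kb at toy scale |
| crossover_rate | 0.5 /meiosis/Mb | scale choice, see below |
| genotype_error_rate | 0.001 | high-coverage call error after filtering |
| depth mean / dispersion | 30 / 20 | high-coverage WGS with realistic spread; ~4% of calls dip below DP 15 |
| ρ background | Gamma(0.5, 0.02) per 2 kb | mean 0.01/bp, heavy right tail, essentially never crosses 0.2/bp |
| ρ spike | +0.5/bp over 5 kb | total ρ 2,500 ≫ 500: an unambiguous anomaly |

The crossover rate deliberately exaggerates per-bp recombination: in a
10 Mb toy genome a 2 Mb misjoin must carry appreciable probability of
an odd crossover count per meiosis (P(odd) = (1 − e^(−2λ))/2 ≈ 0.43 at
λ = 1), or the ≥3-of-18 signature the method keys on could not arise at
desk scale at all — the real phenomenon lives on ~150 Mb chromosomes.
Null-calibration runs instead use the realistic mammalian scale,
0.01 events/meiosis/Mb (~1 cM/Mb), no misjoin, no genotyping error and
no ρ spike, and are required to produce no cluster flags and no
candidates. All randomness flows through one seeded generator;
identical seeds give byte-identical VCFs and tracks.

What the simulation does *not* emulate: population structure and real
LD (the ρ track is generated at the track level, where the decision
rule operates — there is no coalescent simulation of unrelated
samples), crossover interference (pure Poisson; the inference uses only
counts and positions), reference/alt base identity (all markers are
A→C), mapping artefacts, and segmental duplications. Passing tests
therefore demonstrate the correctness of the inference machinery and
its calibration under the stated generative model, not robustness to
every failure mode of real sequencing data.

## Replicate studies and problem sizes

The recovery study plants one 2 Mb inversion in a 10 Mb genome and runs
50 seeded replicates of the full pipeline (9 + 9 meioses, 1 marker per
10 kb, 0.1% genotype error, ρ spike on), scoring break detection,
cluster flags within 50 kb of both breakpoints, a positive LD label,
and integrated corroboration; the null study runs 50 replicates with no
misjoin at the realistic crossover rate. These sizes were chosen so a
full study completes in seconds on one core while keeping every rate
estimate at n = 50.

## Known limitations

* Break detection assumes one assembly is mostly right per chromosome;
  a chromosome that is majority-rearranged yields calls against the
  wrong backbone (reported symmetrically, so the pair of runs A-vs-B
  and B-vs-A exposes this).
* Breakpoint precision is limited to the block boundaries of the input
  alignment.
* Nested events are reported as independent candidates.
* The ≥3-crossover rule's false-positive behaviour depends on marker
  density and the merge window; the defaults are calibrated for the
  simulated densities, and real data with very dense informative
  markers may warrant a narrower `merge_window`.
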