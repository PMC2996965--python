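# Methods

## The assay model

The package models a multiplex double-ARMS reaction on a bead array for one
diploid individual. The template is the individual's two chromosome-level
sequences over a shared, gap-free coordinate system (1-based, inclusive
throughout all I/O). Primers are allele-specific: the 3'-terminal base must
match the template for extension, interior polymorphic positions are covered
by IUPAC wobbles so annealing never depends on them.

An amplicon (f, r, chromosome c) forms iff forward primer f and reverse
primer r both anneal to chromosome c — 3' terminus included — with f's
footprint strictly upstream of r's and the product no longer than
`max_amplicon_len` (3,500 bp in multiplex, 10,000 bp single-plex; these are
the empirical product-length ceilings of the bench assay, used here only as
geometry cut-offs — irrelevant for a 237-bp exon but enforced for longer
regions). Both ends must match the *same* chromosome: the model has no
chimeric template, which is exactly the property that makes the readout a
direct cis/trans measurement.

Capture duplicates every product: species (f, r) makes two cells of the
dense (bead class × label primer) table true, (bead f, label r) and
(bead r, label f). One anchored primer per bead class, at most 100 classes
per tube (the spectral address space of the array); requesting more is an
error, never a silent split.

### Noise

Event counts are drawn as `round(max(0, Normal(μ, σ)))` with defaults
195 ± 12 for template-present cells and 9 ± 5 for background — the assay's
observed signal statistics, used as generative parameters because no
generative law is published; the distribution family is a package choice and
every parameter is replaceable. Two error channels:

* `dropout_rate` — a true cell re-drawn from the background distribution
  (a failed solid-phase reaction still shows background events; the
  documented sub-liquid-phase efficiency of solid-phase PCR is represented
  phenomenologically by this rate, not kinetically);
* `false_capture_rate` — a background cell promoted to the positive
  distribution (promiscuous priming / spurious capture).

The reporter/background fluorescence ratio is emitted as events over the
background mean, clamped onto the correct side of the 4× gating rule for
the distribution the cell was drawn from (a ≳6σ background excursion could
otherwise cross the gate and break the two-observable contract). Event count
and ratio are deliberately two separate observables, because the decoder
applies two separate rules to them.

Every noise model must carry a seed; an unseeded simulation is an error.
Cohort runs derive one stream per (individual, tube) from a single base seed
by fixed offsets, so any readout can be regenerated in isolation and panel,
cohort and assay stages are independently reproducible.

## Positivity and decoding

A cell is positive iff events ≥ 100 **and** ratio ≥ 4 (both bounds
inclusive — "a threshold of 100" and "at least four fold" read as inclusive).
A reaction (f, r) is positive iff both its duplicate cells pass (the
both-beads rule; relaxable). With the default parameters the threshold sits
≈ 7.9σ above background-free signal loss and ≈ 18σ above background, so the
two regimes essentially never cross.

Genotype calling: a site's base set is the union of reference-sense
discriminated bases of its primers appearing in positive reactions.
`min_base_support` demands that many independent reactions per base; cohort
decoding defaults to 2, because the layouts test every site against many
partners — a genuine variant collects support from each of them while an
isolated false capture rarely exceeds one. Sites with zero surviving
coverage are recorded as missing and rendered as gaps, not failed
individuals. Sites with more than two bases make the individual
`conflicted`.

Phase assembly two-colours the heterozygous sites. Each positive reaction
between two het sites asserts a cis pair; per site pair, coupling and
repulsion orientations are tallied by summed reaction support and the
majority wins (a tie, or any disagreement in `strict` mode, gives
`conflicted`). Constraints naming a base the genotype calls do not carry are
discarded first. The seed is the lexicographically smallest het site —
haplotype labels are arbitrary, so all comparisons are over unordered pairs
— assignments propagate by BFS over the orientation graph, a global re-check
over every edge catches parity-inconsistent cycles (`conflicted`), and het
sites disconnected from the seed's component give `ambiguous` with the
blocks listed. Homozygous sites are copied onto both haplotypes. The decoder
emits one haplotype for a fully homozygous individual, two otherwise, never
more.

The exhaustive oracle enumerates all `2^(h−1)` phase configurations of the
h het sites (guarded at h ≤ 12), predicts each candidate pair's zero-noise
positive set by direct primer-template matching on reconstructed full-length
sequences, and keeps the configurations whose prediction equals the
observation. Decoder `ok` must coincide with a unique survivor; the suite
checks this equivalence on 500 random diploids over an eight-site panel.

## Primer design

One split primer per observed base per site and orientation: the 3' terminus
sits exactly on the site, the footprint grows upstream (or downstream, for
reverse primers, which are stored 5'→3' as synthesized with descending
reference coordinates ending at the discriminated site). Length is the
shortest in [14, 28] nt whose melting temperature lands in 55 ± 3 °C.

Tm uses the unified nearest-neighbour parameter set (Biopython's `Tm_NN`,
50 mM Na+ defaults); the Wallace rule `2(A+T) + 4(G+C)` is selectable for
exact-arithmetic tests. A wobbled oligo pool has no single Tm, so min, mean
and max over the concrete expansions are reported and the design window
applies to the mean (pools beyond 1,024 expansions are summarized over the
first 1,024 in lexicographic order — deterministic, and far beyond any
realistic primer).

Complementarity screening is degenerate-aware (two codes count as
complementary when any of their expansions would pair, conservative over the
pool): an overall reverse-complement run > 8 nt fails, a 3'-anchored run
> 4 nt fails (extensible duplexes prime artefacts). The thresholds are
heuristics — the bench goal is stated but unquantified — and configurable.

A site/base with no feasible length yields no primer plus a logged
diagnostic, never an exception. The simulation pipeline
(`design_full_panel`) instead takes the closest-Tm length and skips the
screens: a simulated assay must not silently lose coverage of a site because
a random backbone was thermodynamically awkward, and the screens are a
design-report tool, not a physical constraint of the simulator.

Published primer tables are parsed from a plain TSV dialect; the
allele-discrimination set is taken from the label suffix (e.g. "g/a/t"),
since the printed bold markup distinguishing wobbles from discrimination
positions does not survive transcription. The span/length invariant is
checked on load; `coord_policy="anchor3"` repairs a misprinted span from the
3' coordinate, which three rows of the packaged table need.

## Reaction layout

The designed pair list is chain-plus-skip: every site with its nearest and
next-nearest downstream partners ((1,2), (2,3), (1,3) on three sites). But
pair-list connectivity is not enough to phase every genotype: homozygous
sites cannot relay phase, so two heterozygous sites separated only by
homozygous ones must be tested *directly*. Because all forward × reverse
primer combinations in a tube co-amplify, co-location is the real design
variable: sites are split into contiguous blocks and one tube is built per
block pair, which places every pair of sites in at least one shared tube
while each tube stays under the 100-bead-class cap. A study-scale panel
(60 sites, ~280 split primers) packs into 6 blocks / 15 tubes of ≤ 100
classes. Sites with no legal partner are listed as uncovered, not fatal.

## The synthetic cohort

The generator emulates the study conditions: a 237-bp alignment with 60
polymorphic sites kept ≥ 30 columns from the edges (so any primer footprint
fits), 33 alleles pairwise distinct at the sites, every intended base
observed at every site, 25% of sites tri/tetra-allelic (the published panel
reports a biallelic majority with a substantial multiallelic minority;
triallelic dominates 70/30 within that share), allele frequencies defaulting
to the published 33-allele spectrum renormalized, and 109 diploid
individuals drawn i.i.d. under Hardy-Weinberg equilibrium. A custom mating
mode draws ordered allele pairs from an explicit joint table — the hook for
cohorts that violate random union of gametes.

What it does **not** emulate: mutation or recombination processes, pedigree
structure, selection, sequence-composition realism (the backbone is uniform
random), PCR kinetics, primer-competition thermodynamics, or cytometer
channel mechanics. Passing tests therefore demonstrate the decoding logic
and estimator algebra under the stated noise model — not robustness to
thermodynamic failure modes real primers meet.

## Population statistics

Frequency tables count chromosomes (two per individual; conflicted or
ambiguous individuals are excluded, logged, and n adjusted) and report
percent to one decimal with raw counts carried alongside. Novel haplotypes —
combinations of known site variants matching no panel allele — get
deterministic `NOVEL-NNN` names in first-seen order under sorted individual
IDs. Published-style tables printed as percentages are re-integerized as
`round(pct/100 × 2n)`, the only convention consistent with the packaged
table's 0.9%/0.5% rows at 218 chromosomes.

Composite LD uses the within-locus Hardy-Weinberg departure terms in its
denominator by default (this bounds |r| by 1, since Δ̂ is half the sample
covariance of the two allele-count vectors and each denominator factor half
a variance); a simple `p(1−p)` denominator is selectable because the source
material does not print its formula. Direct LD is the gametic estimator on
phased chromosomes. Monomorphic sites raise an explicit error rather than
returning NaN. The published study-specific values for its positions 8/233
comparison cannot be recomputed without the unpublished raw genotypes; the
package instead verifies the estimator identity (agreement under random
mating within Monte-Carlo error, separation in the built direction on a
constructed HWE-violating cohort).

## Problem sizes and tolerances in the test suite

The suite exercises: the full study scale (60 sites, 33 alleles, 109
individuals, 15 tubes) at zero noise — 100% haplotype recovery and exact
frequency counts — and at 0.5% dropout/false-capture — ≥ 99% recovery; a
1,000-individual ten-site cohort at 1% error rates for decoder robustness;
500-genotype oracle equivalence on eight sites; and n = 10,000 two-locus
cohorts for the LD identity with a 3-Monte-Carlo-SE tolerance
(SE ≈ (1−r²)/√n). These sizes keep the default run around half a minute
while leaving every statistical margin several σ wide.

## Known limitations

* The assembler's support-majority vote is a package choice; the bench
  method motivates redundancy but prescribes no vote rule. `strict` mode
  refuses any conflict instead.
* Dropout and false capture are i.i.d. per cell; correlated failures (a bad
  tube, a failed wash) are not modeled and would defeat the duplicate-cell
  QC more often than the independent model suggests.
* The oracle reconstructs uncovered polymorphic columns with the
  column-majority base; if a primer's discriminating site were uncovered by
  the genotype calls this fill could bias its predictions, so oracle use
  assumes full site coverage (true of the layouts shipped).
* Tm estimation ignores mismatch thermodynamics entirely: the 3'-mismatch
  rejection is modeled as absolute, whereas real ARMS discrimination is
  kinetic and imperfect (that leakiness is what `false_capture_rate`
  phenomenologically absorbs).
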