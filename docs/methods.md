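# Methods

This note documents the models and procedures `sd1hap` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical/design choices made where the design was open.

## The locus model

All twelve haplotype definitions are shipped verbatim in Nipponbare
IRGSP-1.0 chromosome-1 coordinates (`sd1hap/data/haplotype_definitions.tsv`)
and mapped onto a synthetic 25-kb locus by a single fixed offset
(`CHR1_OFFSET = 38,372,465`; locus = chr1 − offset), so published positions
remain quotable in reports.

The synthetic gene is forward-strand with three exons and two introns. Its
layout was derived by solving the published diagnostic coordinates for a
consistent codon frame: with exon 1 at locus 10,001–10,450, intron 1 of
102 bp, exon 2 at 10,553–10,999, intron 2 of 1,471 bp and exon 3 at
12,471–12,743 (CDS = 390 codons), the residue-94/100 sites fall in exon 1,
the residue-240/266 sites and the C→T marker linked to the 383-bp deletion
fall in exon 2, and the residue-300/340/342/349 sites fall in exon 3 — every
one of them at the codon position its amino-acid change requires (e.g.
GGA→GAA at the second codon base for Gly100Glu, TAC→TAA at the third for
Tyr342\*). The gene end, 12,743, maps back to chr1 38,385,208, the anchor of
the published ±10-kb analysis window. One published coordinate is not
reconcilable with this (or any) frame: the 2-bp indel at 38,382,846–847
lands in codon 127/128, not codon 130 as its "Arg130fs" description implies;
the shipped table keeps the published detail string as metadata while the
annotator reports the codon it actually computes. The indel itself is
encoded as a 2-bp deletion (the prose description), configurable to an
insertion (the tabulated description); the two sources disagree.

Diagnostic codons are pinned; all other codons are drawn uniformly from the
61 non-stop codons, intergenic/intronic sequence is uniform random, and
splice dinucleotides are canonical GT/AG. Identical `SimConfig` (including
`seed`) gives byte-identical FASTA/VCF/TSV outputs.

## Synthetic cohort

`simulate_cohort` builds `n_per_class` accessions per haplotype (default
composition mirrors the published distribution: types 3–6 *japonica*, 7–10
*indica*, type 12 *aromatic*, mixed pools for types 1/11) plus optional
GR/EQ heterozygotes — heterozygous at the residue-100/340 sites only, the
heterozygote class the source cohorts actually report. Heterozygous
structural alleles are not simulated: zygosity is not derivable from the
insert-size evidence rule, so they would be unlabellable by construction.

The cohort VCF is joint-called style: carriers get homozygous-alt genotypes
with Poisson(coverage) depth and alt fraction 1.0, non-carriers explicit
0/0, heterozygotes 0/1 with binomial alt fractions, and genotypes falling
inside an accession's own deletion are missing with depth 0 (no reads map
there). Long deletions are symbolic `<DEL>` records with INFO/END; the 2-bp
indel carries explicit alleles.

Plant heights are Normal(group mean, `height_sd = 8 cm`). Defaults place the
wild type and ER at 150 cm, EQ at 110 cm, the *japonica* point mutants
(types 3–5) near 58–60 cm — the shortest groups, as reported — and the other
loss-of-function classes at 85–95 cm. These means are chosen once to
reproduce the qualitative ordering of the published phenotype comparison
(semi-dwarf classes separable from wild type by ANOVA letters at these
sample sizes), not its exact values, which depend on field conditions.

## Read-pair model and deletion detection

Fragments are placed uniformly on the accession sequence with truncated-
Normal lengths (`insert_mean = 400`, `insert_sd = 30`, truncated to
[2·read_length, locus]; read length 100 bp, coverage 30×; the source
datasets' library parameters are unpublished, so these are free parameters
set to typical short-read resequencing values). Pairs are reported in
reference coordinates as after realignment: a fragment spanning a deletion
junction has its template length inflated by the deletion length. Reads
that would cross a junction are dropped, standing in for alignment
clipping; the practical consequence is that every emitted spanning pair's
inner span contains the true deleted interval, which is what lets the
caller's intersection interval bracket the truth. The generator does not
model base qualities, sequencing error, FASTQ output, recombination or
selection.

Detection: the insert model is fitted robustly (median, 1.4826·MAD, scale
floored at 1 so degenerate constant libraries remain usable); FR pairs with
template length strictly above μ + 4σ are discordant; clusters are maximal
sets of mutually overlapping inner spans. Because intervals have the Helly
property, such sets are exactly the spans sharing a common point, found by
a max-coverage sweep taking the largest cluster first — this makes the call
robust to an isolated random discordant pair landing near a real cluster,
which with 3,750 pairs per accession happens at an appreciable rate
(P(TLEN > μ+4σ) ≈ 3×10⁻⁵ per pair). Calls need ≥ 3 supporting pairs;
`coverage_drop` flags mean inside-depth below 10% of the 500-bp flanking
depth, which distinguishes homozygous deletions. `k_sigma = 4` and
`min_support = 3` are exposed in configuration; no numeric thresholds for
this evidence rule are published, and these defaults put the per-accession
false-cluster probability far below one while keeping ~25–30 supporting
pairs for a 383-bp deletion at 30×.

## Genotype filtering

Sites are filtered per genotype at depth > 5 and alternate-read fraction
> 0.8, both strict, matching the published wording. The fraction rule is
applied to homozygous-alt claims only: a true heterozygote sits near 0.5
and would be categorically removed by a literal reading, leaving
heterozygosity — which the classifier must report — unobservable, so het
calls are retained on the depth bound alone. Failing calls are removed,
never modified, and a site is dropped when no non-reference call survives.
The alternative interpretation of "SNP frequency" as a population-level
frequency is deliberately not implemented; the filter precedes cohort
aggregation.

## Classification

Precedence is structural (1) → homozygous point LOF/frameshift (2) →
residue-100/340 combination (3), because accessions carrying type 3–12
diagnostics can simultaneously carry readable 100/340 states. A deletion
call matches a defined interval at reciprocal overlap ≥ 0.9 (configurable;
insert-size breakpoints are imprecise by roughly a read length per side,
and 0.9 accommodates that for a 383-bp event at these library parameters).
Two distinct structural matches raise a conflict error — the signature of
the seed-purity problems known in germplasm collections. G/Q, absent from
natural populations, is a reportable label rather than an error: absence is
a finding. If several distinct point diagnostics match (possible only on
contaminated input), the lowest type id wins deterministically and all
evidence is recorded. Expected alternate nucleotides at diagnostic sites
are derived from the stated amino-acid changes through the genetic code on
the synthetic CDS; only the C→T at 38,383,221 is published directly.

Frequency tables count homozygous calls only by default (heterozygotes are
excluded from numerator and denominator, following the published tables'
footnote), broken down by subpopulation or landrace/modern category, with
percentages to one decimal.

## Diversity statistics

`diversity_stats` removes every column containing a gap/missing/ambiguous
state (complete deletion — the convention the statistics were reported
under), then counts *S*, η = Σ(alleles − 1) (so η ≥ *S* at multi-allelic
columns), *k* as the mean over all n(n−1)/2 pairs, π = *k*/L_used,
θ per sequence = η/a₁ and θ_w per site = η/(a₁·L_used). Tajima's *D* uses
the 1989 constants and is undefined for S = 0 or n < 4; significance uses
the scaled-beta approximation of the D distribution (the default in DnaSP),
not tabulated confidence limits. Windows are [gene_start − flank,
gene_end + flank] with 1-kb and 10-kb default flanks. Pairwise deletion is
available where the phylogenetic stage needs it.

The neutral simulator is msprime's Hudson coalescent, no recombination,
infinite sites (continuous genome), with the per-locus mutation rate set so
E[pairwise differences] = θ and E[S] = θ·a₁(n); mutations are assigned to
integer alignment columns (collisions resolved to the next free column,
negligible at the sizes used). Recovery tests run n = 20, θ = 5 over 1,000
replicates on 1-kb sequences — the statistics are per-locus, so the
sequence length only needs to dominate the site count. The observed mean
*D* is slightly negative (≈ −0.08), the documented finite-sample property
of the statistic, and lies within three standard errors of zero.

One-way ANOVA with all-pairs Tukey HSD produces the compact letter display:
letters are the maximal cliques of the not-significantly-different graph at
α = 0.05, labelled in descending order of clique mean, so two groups share
a letter iff Tukey does not separate them. SNP-sharing Venn partitions
support 2–5 sets and count every exclusive membership region.

## Phylogenetics

The VCF-derived SNP matrix encodes heterozygotes as IUPAC ambiguity codes
and missing samples as N. Distances are Tamura–Nei 1993 with base
frequencies pooled across all sequences and per-pair transition/
transversion proportions — an approximation of MEGA's "Maximum Composite
Likelihood" distance that shares information across pairs the same way but
does not reproduce the full simultaneous estimation, so agreement with MEGA
is expected at topology level, not to distance bit-exactness. Pairwise
deletion skips, per pair, sites ambiguous in either sequence; saturated
pairs (non-positive logarithm arguments) are flagged inestimable, and JC69
and raw p-distance are available as downgrades — the pipeline falls back to
p-distance automatically when a sparse SNP-only matrix saturates TN93, and
records that in its manifest.

Neighbor joining is the standard Saitou–Nei Q-criterion agglomeration.
Ties break on the lexicographically smallest pair of cluster
representatives (each cluster represented by its smallest leaf label), so
topologies are deterministic; negative branch lengths are clamped to zero
with the deficit moved to the sister branch, preserving the pair distance.
Bootstrap resamples alignment columns with replacement; supports attach to
the point-estimate tree's internal bipartitions (the MEGA convention, not a
majority-rule consensus); replicates with an inestimable pair are dropped
and counted; edges below the collapse threshold (default 60%) are
contracted into polytomies.

## Tandem repeats

A TR locus is a maximal run of s[i] = s[i−p] covering at least two full
copies, reported under the minimal period of the run (computed from the
KMP border), with fractional trailing copies allowed. Minimal-period
filtering keeps homopolymers and dinucleotide runs from masquerading as
8–10-bp repeats; within the 8–10 window, Fine–Wilf makes it impossible for
a reported run to carry two distinct in-range periods, so each maximal run
is reported exactly once, left-most phase. Units match up to cyclic
rotation (run phase is arbitrary) and projected starts must agree within
50 bp; reference loci inside a deleted interval are counted lost with a
flag. The scanner is validated by exhaustive agreement with a brute-force
oracle that tests every (start, period, span) by direct character
comparison.

## Problem sizes and limitations

Default analysis sizes — 120–130-accession cohorts at 30×, 1,000 neutral
replicates, 100-tree NJ consistency sweeps, 200 oracle sequences — are the
package's chosen verification scale; all complete in seconds to tens of
seconds. What passing these tests shows is that the pipeline's inference
is correct under its own generative assumptions (uniform coverage,
Gaussian inserts, error-free genotypes at stated depths, no recombination
or population structure within the locus). It does not show robustness to
alignment artefacts, reference bias, index hopping or segmental
duplication, none of which the generator emulates. Protein-structure
modelling, geographic plotting, genome-browser rendering and reanalysis of
the real 3K/wild-rice datasets are out of scope; the `Hd1` companion locus
appears only as a metadata join slot.
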