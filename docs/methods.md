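# Methods

This note documents the models, parameter choices and numerical
conventions behind `plastovar`, and what the synthetic cohort does and
does not emulate.

## The synthetic cohort

The generator is the package's definition of the study conditions; all
stages are validated against its truth tables.

**Genomes.** A random base plastome is laid out quadripartite —
LSC 56.25%, IRb 16.25%, SSC 11.25%, IRa 16.25% of the genome length
(the proportions of a typical 160 kb plastome; the demo uses 20 kb so
the whole pipeline runs in seconds, and the proportions are preserved).
IRa is maintained as the exact reverse complement of IRb in every
emitted genome.  Genus ancestors derive from the base by substitutions
only, with the plastome conservation gradient: the configured
divergence applies to the LSC, SSC mutates at 0.6× that rate and the
IRs at 0.05×, mirroring the well-known pattern that IRs are nearly
identical across genera while single-copy regions diverge strongly.
Substitution-only divergence keeps all genomes of a cohort on one
coordinate frame, which is what makes the alignment-free column-scan
oracle and the capture conservation track possible.  Defaults: three
genera (an alder-like focal genus at divergence 0 carrying the planted
variants, plus birch-like 0.20 and willow-like 0.25 relatives).

**Planted variants.** The focal panel defaults to 7 individuals
(4 Taymyr, 1 Omoloy, 2 Kolyma) and an alder-like inventory: 16 SNPs
(8 transitions, 8 transversions), 5 InDels, 13 homopolymer-run length
differences, each either region-shared (all individuals of one region
carry the alternate allele; the regions are cycled) or private to one
individual.  Variants are planted in single-copy regions only (IR
planting is optional and mirrored), kept ≥15 bp apart, and placed so
their leftmost representation is unique: deletions/insertions start
with a base different from their left neighbour and contain at least
two distinct bases (so they can never be mistaken for homopolymer
changes), homopolymer edits operate on runs ≥4 whose anchor base
differs from the run base.  InDels and homopolymer edits avoid gene
features.  Truth tables store the minimal VCF-style anchored alleles —
the same convention the scanner emits — so truth comparison is exact
string equality.

**Reads.** Fragments are drawn per sample from a genus mixture
(default mixtures shift from alder-rich at 6,700 cal yr BP to
willow-dominated at 60 cal yr BP), uniformly on the circle (reads may
wrap the origin), with truncated-normal lengths (mean 60, sd 15,
min 30 nt — aDNA-like without claiming any particular study's
distribution).  Deamination converts C→T at offset i from the 5′ end
with probability p_max·exp(−decay·(i−1)) and G→A symmetrically from
the 3′ end (defaults p_max 0.3, decay 0.3 — strong, clearly ancient
damage); a uniform baseline error (default 0.001) follows.  Because
sedaDNA is predominantly of local origin, a sample with a
`local_region` set draws its fragments from that region's individuals.
PCR duplication is modelled as geometric resampling of emitted
fragments at a configurable rate.

**Capture.** The bait is a fourth, larch-like taxon built from the
base ancestor at divergence 0.35 with the same conservation gradient,
so only the conserved regions (essentially the IRs) of any cohort
genus hybridise.  A read is retained with probability 0.9 if the
100 bp window around its source midpoint has ≥90% identity to the
bait, and 0.02 otherwise.  Window lookup uses ancestor coordinates;
the few tens of bp of planted-InDel shift are negligible against the
window size.  Capture output is therefore strongly enriched for
conserved-region fragments — which is exactly why capture-based
abundance is bait-biased while shotgun abundance is not (the analysis
drivers report shotgun-based proportion recovery for this reason).

**What the generator does not emulate:** paired-end reads and read
merging, library-prep artifacts beyond duplication, rearrangements,
IR boundary shifts, polymerase slippage (homopolymer variation is
planted, not emergent), contamination, and a realistic >8,000-genome
database (the classifier database is the cohort itself).  Passing
tests therefore demonstrate correctness of the algorithms under these
idealised conditions, not performance on real sediment libraries.

## Alignment and variant scanning

Collinearity is assumed; anchor chains that are <50% collinear raise a
rearrangement error rather than being resolved.  Unique shared 24-mers
are chained by longest increasing subsequence; inter-anchor segments
are aligned with edlib (unit-cost global alignment), and every gap run
is shifted to its leftmost score-equivalent position, which is exactly
the VCF left-alignment convention.  Pairwise alignments against the
chosen reference are merged into a reference-anchored MSA; insertions
from different genomes at the same reference slot share columns only
when their inserted strings are identical.  Positions are 0-based
half-open internally and 1-based in all reports.  Identity between two
sequences is identical columns over total alignment columns, gap
columns included in the denominator — the convention under which
cross-genus plastome identities come out low.

Classification rule order (homopolymer before InDel before SNP) plus
the run ≥4 threshold keeps slippage-prone sites out of the SNP and
InDel inventories; the threshold is our choice — small enough to catch
poly-A/T/G differences, large enough not to reclassify ordinary
1–3 bp repeats.

## Statistical parsimony

The connection limit uses the probability that j mutations between two
aligned sequences of length L strike j distinct sites under uniform
per-site mutation, P_j = ∏_{i=1..j}(1 − i/L), and returns the largest
j with P_j ≥ α (default α = 0.95).  This no-superimposed-change
probability is the quantity statistical parsimony bounds; it is
monotone in L and guarantees distance-1 connections for any L ≥ 100.
The implementation evaluates the product in log space; tests and the
acceptance script cross-check it against an exact `fractions.Fraction`
evaluation.  Network construction is agglomerative with deterministic
tie-breaking by (distance, lexicographic id pair); PopART's internal
order is unspecified, so determinism was chosen over mimicry.

## Classification and abundance

The classifier is a two-level (root → genus) canonical 31-mer majority
vote: k-mers unique to one genus vote for it, shared k-mers collapse
to the root; assignment needs a strict majority of hit k-mers and ≥2
genus votes, ties stay unclassified.  It is exact-match by design —
deaminated bases simply cost k-mers — and strand-symmetric by
canonicalisation.

Raw classified counts under-represent genera whose genomes the
database covers symmetrically (conserved IRs collapse to the root for
everyone, but the chance that a read still contains genus-unique
k-mers differs between genera).  Mixture proportions are therefore
sensitivity-corrected: each genus's classifiability is measured by
tiling its own database genomes into damage-free pseudo-reads of the
observed read length and classifying them against the same index, and
proportions are n_t/s_t renormalised.  The correction uses only the
database, never the truth tables.

Relative abundance follows the three-taxon convention: a taxon's
post-deduplication read count as a percentage of the summed counts of
the three genera within one (sample, method), rounded to 2 decimals in
reports; all-zero samples are flagged undefined rather than divided.

## Mapping, duplicates, damage

The mapper seeds with exact 24-mers (both strands), votes on
diagonals, and extends the best candidates end-to-end with edlib in a
±50 bp window; the best alignment wins by fewest edits, then leftmost
reference position, then forward strand.  Thresholds are presets:
ancient (mismatches ≤5% of read length, gap bases ≤5%, single gap
≤50 bp) and modern-scaffold (20%/10%/50).  The reference is padded
with its own prefix so origin-wrapping fragments align end-to-end;
coordinates are folded back to [0, L).

Unit-cost alignment can represent a damaged terminal base as a
cost-tied insertion or near-terminal deletion instead of a mismatch;
gap runs within 10 columns of either read end are re-expressed as
aligned columns whenever that does not increase the edit cost, so
terminal substitutions — the damage signal — survive representation
ties.  Damage profiles are computed from alignments made with the
permissive preset: the strict 5% threshold censors precisely the most
damaged (and short) reads and biases terminal rates downward, whereas
estimating damage before strict filtering recovers the simulated
rates within ±0.02 at 50k reads.

Duplicates are defined by the full coordinate triple (start, end,
strand) per reference — single-end simplification of coordinate-based
duplicate marking — keeping the highest quality sum; marking is
idempotent and order-invariant, and duplicate marking is applied
within each (sample, method) library, since PCR duplicates cannot span
libraries.  Breadth of coverage is computed after deduplication (a
flag restores the with-duplicates variant); insertions contribute no
reference depth.

## Variant tracking

Only sites already discovered in the modern panel are evaluated.  SNP
sites count the bases of deduplicated reads spanning the position;
InDel sites require the read to span the whole event plus one anchor
base each side; homopolymer sites are tallied as run lengths over the
entire reference run and re-expressed in the scanner's minimal
anchored form (prefix-matching alone is ambiguous when the alternate
allele is a prefix of the reference run).  The ancient allele is the
unique majority; ties are conflicts, never resolved silently.  A
C→T (G→A) supporting read within 10 bp of its sequenced 5′ (3′) end
marks support as damage-explicable; an allele is damage-suspect when
at least half its support is explicable.  Suspect alleles are reported
by default and excluded only in strict mode.  A marker for the core's
own region is confirmed when every covered evaluation shows its
allele and refuted otherwise; a marker for a different region is
confirmed-as-absent when the local core lacks its allele.

## Problem sizes

The test suite and acceptance script run the full pipeline on 20 kb
genomes (preserving quadripartite proportions), 7-individual panels,
up to 50 planted variants, read sets of 2,000–50,000 fragments, and
ten generator seeds for the scanner check — sizes chosen so each
statistical check has comfortable power (binomial bounds at 3 SDs,
damage recovery at ±0.02) while a complete run stays in the
tens-of-seconds range on one core.

## Known limitations

The aligner targets near-identical collinear genomes (identity floor
80%) and is not a general aligner; the classifier cannot reproduce
tool-to-tool differences between production classifiers; the parsimony
probability is the uniform-mutation no-multiple-hit form, without
coalescent corrections; capture simulation models conservation-gated
retention, not hybridisation thermodynamics; homopolymer and InDel
positions are only meaningful relative to the chosen reference frame.
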