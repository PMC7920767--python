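# plastovar

Chloroplast-genome variant analysis for shrub taxa, from modern plastome
panels down to sedimentary ancient DNA (sedaDNA): variant scanning over
whole-plastome alignments, statistical-parsimony (TCS-style) haplotype
networks, region-diagnostic marker screening, k-mer LCA read
classification, short-read mapping with duplicate removal, terminal
deamination profiling, and allele tracking of modern variant positions
through time in lake-sediment reads.

## Who this is for

Researchers comparing a small panel of near-identical plastome
assemblies (e.g. *Alnus alnobetula*, *Betula nana*, *Salix* sp.
individuals sampled across regions) with shotgun and hybridization-
capture sedaDNA from a sediment core, and who want every stage of that
comparison reproducible and testable.  Because public read data and
GenBank assemblies are not always at hand, the package ships a
first-class synthetic-cohort generator that emulates the study system —
quadripartite plastomes (LSC / IRb / SSC / IRa, with IRa the reverse
complement of IRb), planted SNP / InDel / homopolymer variants with
regional structure, short (30–120 nt) fragments with terminal
C→T / G→A deamination, and a conserved-region capture filter — together
with truth tables that make every stage verifiable.

## The core methods

* **Variant scanning.** Collinear plastomes are aligned by chaining
  unique shared 24-mers and aligning inter-anchor segments; gap runs
  are left-normalised (VCF convention).  Every column with ≥2 alleles
  becomes a site classified in rule order: a pure length change of base
  X inside a mononucleotide run ≥4 ⇒ homopolymer; any other gap ⇒
  InDel; single-base substitution ⇒ SNP (transition A↔G / C↔T,
  transversion otherwise).  Coding effects are recomputed per allele
  with translation table 11.
* **Statistical parsimony.** Haplotypes are unique variant combinations;
  distances are absolute allele differences.  The connection limit is
  the largest step count j whose parsimony probability
  P_j = ∏_{i=1..j}(1 − i/L) still reaches α = 0.95 — the probability
  that j mutations over an alignment of length L all struck distinct
  sites.  Pairs within the limit join through d−1 single-step
  intermediates, in order of increasing distance.
* **Diagnostic markers.** An allele fixed in one region's individuals
  and absent from all others is a candidate biogeographic marker
  (singleton regions flagged, not hidden).
* **sedaDNA tracking.** Reads are quality-trimmed (sliding window 4,
  mean Q ≥ 15, min length 40), assigned to genus by canonical 31-mer
  majority vote with conflicts collapsing to unclassified, mapped by
  deterministic seed-and-extend (word 24; 5%-mismatch ancient preset
  and 20% modern preset), deduplicated by coordinates, and profiled for
  terminal deamination.  Ancient alleles at modern SNP positions are
  tallied from spanning reads, matched against the modern panel, and
  used to confirm or refute each marker for a core of known location.

## Worked example

```bash
plastovar all --seed 1 --outdir results/run
# or the numbered drivers:
python analysis/01_simulate_cohort.py
python analysis/02_scan_variants.py
...
python analysis/07_track_variants.py
```

The default cohort (seed 1, 20 kb genomes, 7 alder-like individuals in
3 regions, four core samples at 60–6,700 cal yr BP) prints:

```
34 variant sites: {'SNP': 16, 'homopolymer': 13, 'InDel': 5}
ts/tv split: {'transitions': 8, 'transversions': 8, 'multiallelic': 0}
pairwise differences (SNPs+InDels): min 2, max 15
connection limit 44 steps at alpha=0.95; 1 component(s), 16 inferred intermediates
16 candidate markers: {'Taymyr': 5, 'Omoloy': 6, 'Kolyma': 5}
largest |estimated - true| proportion across shotgun samples: 0.020
variant sites evaluated: 34, covered by sedaDNA reads: 34, conflicts: 0
  Taymyr: confirmed_by_ancient x5
```

Reading: the scanner recovered all 34 planted variants with the exact
8/8 transition/transversion split that was planted; the parsimony
network connects all haplotypes within the 95% limit; sixteen sites are
region-diagnostic candidates; genus mixture proportions estimated from
classified shotgun reads are within 2 percentage points of the
simulated truth; and every covered Taymyr marker is confirmed by the
(simulated, Taymyr-local) ancient reads.

A bundled table of published per-sample read counts
(`plastovar.datasets.sediment_read_counts()`) provides a real-data
worked example for the abundance arithmetic: e.g. capture counts
{Alnus 1072, Betula 37, Salix 1164} at 6,700 cal yr BP give relative
percentages {47.16, 1.63, 51.21}.

`analysis/08_replicate_genbank.py` optionally reruns the variant scan
on the deposited GenBank plastome assemblies; it needs network access
(or pre-downloaded FASTAs under `data/genbank/`).

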