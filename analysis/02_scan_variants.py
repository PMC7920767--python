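#!/usr/bin/env python
"""Align the alder-like panel, scan variant columns, and tabulate the
inventory: SNPs with transition/transversion split, InDels, homopolymer
run differences, plus pairwise difference counts.

Writes results/run/: alignment.fasta, variants.tsv, variants.vcf, and
results/pairwise_differences.tsv.
"""

from plastovar.alignment import count_ts_tv, pairwise_differences
from plastovar.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(outdir="results/run", seed=1, n_reads_per_sample=5000)
bundle = run_pipeline(cfg, through="variants")

sites = bundle["sites"]
classes = {}
for s in sites:
    classes[s.var_class] = classes.get(s.var_class, 0) + 1
print(f"{len(sites)} variant sites: {classes}")
print(f"ts/tv split: {count_ts_tv(sites)}")

diffs = pairwise_differences(sites)
inds = [i for i in diffs.index if i != bundle["ref"].id]
sub = diffs.loc[inds, inds]
print(f"pairwise differences (SNPs+InDels): min {sub.values[sub.values > 0].min()}, "
      f"max {sub.values.max()}")
sub.to_csv("results/pairwise_differences.tsv", sep="\t")
print("wrote results/pairwise_differences.tsv")
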