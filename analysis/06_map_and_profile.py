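#!/usr/bin/env python
"""Map genus-extracted reads to their draft plastomes, remove PCR
duplicates, and compute the per-sample abundance table (read counts,
breadth of coverage, relative %) plus the terminal deamination profile.

Writes results/run/: abundance.tsv, damage.tsv.
"""

from plastovar.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(outdir="results/run", seed=1, n_reads_per_sample=5000)
bundle = run_pipeline(cfg, through="stats")

ab = bundle["abundance"]
print("abundance table (post-dedup counts, breadth %, relative %):")
print(ab.to_string(index=False))

dmg = bundle["damage"]
if dmg is not None:
    print("\n5' C->T frequency, offsets 1-5:",
          ", ".join(f"{v:.3f}" for v in dmg.ct5[:5]))
    print("3' G->A frequency, offsets 1-5:",
          ", ".join(f"{v:.3f}" for v in dmg.ga3[:5]))
    print(f"interior baseline mismatch rate: {dmg.baseline:.5f}")
print("\nwrote results/run/abundance.tsv and results/run/damage.tsv")
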