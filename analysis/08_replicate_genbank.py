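#!/usr/bin/env python
"""Optional replication on the deposited plastome assemblies (needs the
GenBank FASTA files, hence network access or a pre-downloaded copy).

Expected inputs under data/genbank/ (one FASTA per accession):
  MT872517-MT872523  seven Alnus alnobetula individuals
  MT872524-MT872530  seven Betula nana individuals
  MT872531           the Salix sp. individual
  KP019639           the Salix purpurea reference

With those present, this driver runs the variant scan on each panel and
prints the SNP inventories and the Taymyr diagnostic-marker count.  If
the files are absent it tries NCBI E-utilities once and otherwise exits
with instructions; the synthetic end-to-end checks elsewhere in this
repository stand in for this replication offline.
"""

import os
import sys
import urllib.request

ALNUS = [f"MT8725{n}" for n in range(17, 24)]
BETULA = [f"MT8725{n}" for n in range(24, 31)]
SALIX = ["MT872531", "KP019639"]
DATA_DIR = "data/genbank"

ALNUS_REGIONS = {  # sampling regions of A01..A07 in deposited order
    "MT872517": "Taymyr", "MT872518": "Taymyr", "MT872519": "Taymyr",
    "MT872520": "Taymyr", "MT872521": "Omoloy", "MT872522": "Kolyma",
    "MT872523": "Kolyma",
}


def fetch(acc: str, path: str) -> bool:
    url = ("https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
           f"?db=nuccore&id={acc}&rettype=fasta&retmode=text")
    try:
        with urllib.request.urlopen(url, timeout=30) as r, open(path, "wb") as fh:
            fh.write(r.read())
        return True
    except Exception as exc:  # noqa: BLE001
        print(f"  could not fetch {acc}: {exc}")
        return False


def load_panel(accessions):
    from plastovar.io import read_fasta

    genomes = []
    for acc in accessions:
        path = os.path.join(DATA_DIR, f"{acc}.fasta")
        if not os.path.exists(path):
            os.makedirs(DATA_DIR, exist_ok=True)
            if not fetch(acc, path):
                return None
        recs = read_fasta(path)
        rec = recs[0]
        rec.id = acc
        genomes.append(rec)
    return genomes


def scan_panel(name, accessions, reference):
    from plastovar.alignment import count_ts_tv, scan_variants, align_plastomes

    genomes = load_panel(accessions)
    if genomes is None:
        return None
    aln = align_plastomes(genomes, reference)
    sites = scan_variants(aln)
    snps = [s for s in sites if s.var_class == "SNP" and not s.ambiguous]
    print(f"{name}: {len(snps)} SNPs ({count_ts_tv(sites)}), "
          f"{sum(s.var_class == 'InDel' for s in sites)} InDels, "
          f"{sum(s.var_class == 'homopolymer' for s in sites)} homopolymer diffs")
    return sites


def main() -> int:
    sites = scan_panel("Alnus panel", ALNUS, ALNUS[0])
    if sites is None:
        print("\nGenBank data unavailable; place the accession FASTAs under "
              f"{DATA_DIR}/ and rerun.")
        return 1
    from plastovar.markers import screen_region_diagnostic

    markers = screen_region_diagnostic(sites, ALNUS_REGIONS)
    from collections import Counter

    print("diagnostic candidates by region:",
          dict(Counter(m.target_region for m in markers)))
    scan_panel("Betula panel", BETULA, BETULA[0])
    scan_panel("Salix vs reference", SALIX, SALIX[1])
    return 0


if __name__ == "__main__":
    sys.exit(main())
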