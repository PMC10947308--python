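#!/usr/bin/env python
"""Bin SNPs into RAD loci, infer haplotypes, and write species-origin codes."""
import sys
from pathlib import Path

from snapmap.cli import main

RUN = Path(__file__).resolve().parents[1] / "results" / "run"

if __name__ == "__main__":
    sys.exit(main([
        "hapcall",
        "--vcf", str(RUN / "genotypes.vcf"),
        "--roles", str(RUN / "roles.tsv"),
        "--out-genotypes", str(RUN / "species_genotypes.tsv"),
        "--summary", str(RUN / "hapcall_summary.json"),
    ]))
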