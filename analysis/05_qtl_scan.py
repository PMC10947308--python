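#!/usr/bin/env python
"""Genome scans with 1000 permutations and stepwise QTL models per trait."""
import sys
from pathlib import Path

from snapmap.cli import main

RUN = Path(__file__).resolve().parents[1] / "results" / "run"

if __name__ == "__main__":
    sys.exit(main([
        "qtlscan",
        "--genotypes", str(RUN / "species_genotypes.tsv"),
        "--map", str(RUN / "map.tsv"),
        "--phenotypes", str(RUN / "phenotypes.csv"),
        "--seed", "1",
        "--out", str(RUN / "qtl.json"),
    ]))
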