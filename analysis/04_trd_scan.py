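#!/usr/bin/env python
"""Scan the mapped loci for transmission ratio distortion."""
import sys
from pathlib import Path

from snapmap.cli import main

RUN = Path(__file__).resolve().parents[1] / "results" / "run"

if __name__ == "__main__":
    sys.exit(main([
        "trdscan",
        "--genotypes", str(RUN / "species_genotypes.tsv"),
        "--map", str(RUN / "map.tsv"),
        "--out", str(RUN / "trd.json"),
    ]))
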