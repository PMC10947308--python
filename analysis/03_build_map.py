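#!/usr/bin/env python
"""Build the linkage map (LOD>=6 grouping, greedy ordering, Kosambi cM)."""
import sys
from pathlib import Path

from snapmap.cli import main

RUN = Path(__file__).resolve().parents[1] / "results" / "run"

if __name__ == "__main__":
    sys.exit(main([
        "map",
        "--genotypes", str(RUN / "species_genotypes.tsv"),
        "--out-map", str(RUN / "map.tsv"),
        "--summary", str(RUN / "map_summary.json"),
    ]))
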