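#!/usr/bin/env python
"""Exact binomial colocalization tests.

Two published worked cases: 3 of 5 QTL falling in reference intervals
covering 11.5% of the genome, and a single trichome QTL against 10 Mb of
candidate region in a 60/0.115 Mb genome.
"""
import sys
from pathlib import Path

from snapmap.cli import main

RUN = Path(__file__).resolve().parents[1] / "results" / "run"

if __name__ == "__main__":
    rc = main(["overlap", "--k", "3", "--n", "5", "--coverage", "0.115",
               "--out", str(RUN / "overlap_qtl.json")])
    if rc:
        sys.exit(rc)
    coverage = 10 / (60 / 0.115)
    sys.exit(main(["overlap", "--k", "1", "--n", "1",
                   "--coverage", str(coverage),
                   "--out", str(RUN / "overlap_trichome.json")]))
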