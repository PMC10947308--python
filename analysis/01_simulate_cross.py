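#!/usr/bin/env python
"""Simulate the study-default outbred F2 cross (216 F2, 8 chromosomes,
~1000 RAD loci, 1% genotype error, 10% distal missingness) into results/run.
"""
import sys
from pathlib import Path

from snapmap.cli import main

RUN = Path(__file__).resolve().parents[1] / "results" / "run"

if __name__ == "__main__":
    sys.exit(main(["simulate", "--seed", "1", "--out-dir", str(RUN)]))
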