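#!/usr/bin/env python
"""Aggregate all stage outputs into results/run/report.json, validating
called species codes against the simulation truth table."""
import sys
from pathlib import Path

from snapmap.cli import main

RUN = Path(__file__).resolve().parents[1] / "results" / "run"

if __name__ == "__main__":
    sys.exit(main(["report", "--dir", str(RUN)]))
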