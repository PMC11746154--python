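#!/usr/bin/env python
"""Download the deposited structures the real-structure tests analyse.

Usage:  python scripts/fetch_structures.py [--dest data/structures]

Fetches mmCIF coordinate files from the RCSB PDB (network required) and
places them under data/structures/ with the lowercase names the test suite
expects.  The files are not redistributed with this repository.
"""

from __future__ import annotations

import argparse
import sys
import urllib.request
from pathlib import Path

ACCESSIONS = ["8URU", "8URQ", "2ZBK", "2Q2E", "1D3Y"]
URL = "https://files.rcsb.org/download/{}.cif"


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--dest", default="data/structures", type=Path)
    args = ap.parse_args()
    args.dest.mkdir(parents=True, exist_ok=True)
    for acc in ACCESSIONS:
        out = args.dest / f"{acc.lower()}.cif"
        if out.exists():
            print(f"{out} already present, skipping")
            continue
        url = URL.format(acc)
        print(f"fetching {url} -> {out}")
        with urllib.request.urlopen(url, timeout=60) as resp:
            out.write_bytes(resp.read())
    print("done")
    return 0


if __name__ == "__main__":
    sys.exit(main())
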