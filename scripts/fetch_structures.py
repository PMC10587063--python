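#!/usr/bin/env python
"""Download the deposited coordinate files the structural benchmarks need.

Run on a machine with network access:

    python scripts/fetch_structures.py --out data/structures

Fetches the experimental structures (PDB 8DMK, 2Y38, 4AQS, 4AQT) from RCSB
and the wild-type predicted-model deposits from ModelArchive.  Afterwards the
deposited-structure benchmarks in tests/test_acceptance.py and the optional
section of scripts/acceptance.py become runnable offline.
"""

from __future__ import annotations

import argparse
import sys
import urllib.request
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from lamnode.benchmarks import MODELARCHIVE_ACCESSIONS, PDB_ACCESSIONS

RCSB = "https://files.rcsb.org/download/{acc}.cif"
MODELARCHIVE = "https://www.modelarchive.org/api/projects/{acc}?type=basic__model_file_name"


def fetch(url: str, dest: Path) -> None:
    if dest.exists():
        print(f"  {dest.name}: already present")
        return
    print(f"  {url} -> {dest}")
    with urllib.request.urlopen(url, timeout=120) as resp:
        dest.write_bytes(resp.read())


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("data/structures"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    for acc in PDB_ACCESSIONS:
        fetch(RCSB.format(acc=acc.upper()), args.out / f"{acc}.cif")
    for acc in MODELARCHIVE_ACCESSIONS:
        fetch(MODELARCHIVE.format(acc=acc), args.out / f"{acc}.cif")
    print("done")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
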