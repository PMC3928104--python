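#!/usr/bin/env python
"""Download the deposited crystal structures used by the validation checks.

Fetches the Ca2+-saturated cardiac troponin core domain (1J1E), the skeletal
troponin structures in both Ca2+ states (1YTZ, 1YV0 — sometimes cited as
"1YVO") and the cTnI N-terminal extension NMR structure (2JPW) into
``data/structures/``.  Needs network access to the RCSB download service;
the test suite reports clearly when the files are absent.

Usage::

    python scripts/fetch_structures.py [--dest data/structures]
"""

from __future__ import annotations

import argparse
import sys
import urllib.error
import urllib.request
from pathlib import Path

ENTRIES = {
    "1j1e": ["1J1E"],
    "1ytz": ["1YTZ"],
    "1yv0": ["1YV0", "1YVO"],  # digit zero in the deposited id
    "2jpw": ["2JPW"],
}
URL = "https://files.rcsb.org/download/{pdb_id}.pdb"


def fetch(dest: Path) -> int:
    dest.mkdir(parents=True, exist_ok=True)
    failures = 0
    for name, candidates in ENTRIES.items():
        target = dest / f"{name}.pdb"
        if target.exists():
            print(f"{target} already present")
            continue
        for pdb_id in candidates:
            url = URL.format(pdb_id=pdb_id)
            try:
                with urllib.request.urlopen(url, timeout=60) as resp:
                    target.write_bytes(resp.read())
                print(f"fetched {pdb_id} -> {target}")
                break
            except (urllib.error.URLError, OSError) as exc:
                print(f"could not fetch {pdb_id}: {exc}", file=sys.stderr)
        else:
            failures += 1
    return failures


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument(
        "--dest", type=Path,
        default=Path(__file__).resolve().parent.parent / "data" / "structures",
    )
    args = parser.parse_args()
    sys.exit(1 if fetch(args.dest) else 0)


if __name__ == "__main__":
    main()
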