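#!/usr/bin/env python
"""Regenerate the packaged reference-network asset and its digest lock.

The reference network is constructed deterministically by
``liversim.reference.build_reference_document`` (its branch fractions and
regulatory weights are the calibrated surrogate parameters recorded there).
This script serializes it to ``src/liversim/data/reference_network.json`` and
writes the SHA-256 regression lock next to it.

Usage:
    python scripts/build_reference.py [--seed N] [--check]

--seed is accepted for interface uniformity; the construction itself contains
no randomness.  --check verifies the shipped asset matches the builder and the
digest without rewriting anything.
"""

import argparse
import hashlib
import json
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from liversim.reference import build_reference_document  # noqa: E402

DATA = pathlib.Path(__file__).resolve().parents[1] / "src" / "liversim" / "data"


def asset_text() -> str:
    doc = build_reference_document()
    return json.dumps(doc.to_dict(), indent=1) + "\n"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0,
                    help="unused (deterministic build); kept for uniformity")
    ap.add_argument("--check", action="store_true")
    args = ap.parse_args()

    text = asset_text()
    digest = hashlib.sha256(text.encode()).hexdigest()
    json_path = DATA / "reference_network.json"
    sha_path = DATA / "reference_network.sha256"

    if args.check:
        ok = json_path.read_text() == text and sha_path.read_text().split()[0] == digest
        print(f"asset {'matches' if ok else 'DIFFERS from'} builder (sha256 {digest})")
        return 0 if ok else 1

    DATA.mkdir(parents=True, exist_ok=True)
    json_path.write_text(text)
    sha_path.write_text(f"{digest}  reference_network.json\n")
    print(f"wrote {json_path} ({len(text)} bytes, sha256 {digest})")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
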