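#!/usr/bin/env python
"""One-time fetch of the 82 study toxin sequences from UniProtKB.

Downloads each entry's JSON, extracts the mature chain (the Chain or
Peptide feature whose length matches the study metadata; falls back to
the full sequence when it already matches), and writes
``data/study_toxins.fasta``. Requires network access; the sequences are
not redistributed with the package.

Usage:  python scripts/fetch_study_sequences.py [--out data/study_toxins.fasta]
"""
from __future__ import annotations

import argparse
import json
import sys
import urllib.request
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from peptarray.study import STUDY_ENTRIES  # noqa: E402

API = "https://rest.uniprot.org/uniprotkb/{acc}.json"


def mature_sequence(acc: str, expected_length: int) -> str | None:
    with urllib.request.urlopen(API.format(acc=acc), timeout=30) as fh:
        entry = json.load(fh)
    full = entry["sequence"]["value"]
    if len(full) == expected_length:
        return full
    for feature in entry.get("features", []):
        if feature["type"] not in {"Chain", "Peptide"}:
            continue
        loc = feature["location"]
        try:
            start = loc["start"]["value"]
            end = loc["end"]["value"]
        except (KeyError, TypeError):
            continue
        if end - start + 1 == expected_length:
            return full[start - 1 : end]
    return None


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", default="data/study_toxins.fasta")
    args = parser.parse_args()

    records = []
    failures = []
    for e in STUDY_ENTRIES:
        try:
            seq = mature_sequence(e.accession, e.length)
        except Exception as exc:  # pragma: no cover - network errors
            failures.append((e.accession, str(exc)))
            continue
        if seq is None:
            failures.append(
                (e.accession, f"no chain of length {e.length} found")
            )
            continue
        species = e.species.replace(" ", "_")
        records.append(f">{e.accession} species={species}\n{seq}\n")
        print(f"{e.accession}\t{e.length}\tok")

    out = Path(args.out)
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text("".join(records))
    print(f"wrote {len(records)} sequences to {out}")
    if failures:
        print("FAILED entries (fix manually):", file=sys.stderr)
        for acc, why in failures:
            print(f"  {acc}: {why}", file=sys.stderr)
        return 1
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
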