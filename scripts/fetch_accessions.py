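#!/usr/bin/env python
"""Fetch the real myoglobin sequences behind the packaged reference panel.

The packaged panels ship with synthetic stand-in sequences so that no test
ever needs the network.  This helper downloads the actual database entries
(UniProt/NCBI accessions) and writes a FASTA + panel config that can be fed
to ``mbstrip run-all`` in place of the fixture.  Requires network access;
never invoked by the test suite.

Usage:
    python scripts/fetch_accessions.py -o accession_panel/
"""

from __future__ import annotations

import argparse
import time
import urllib.request
from pathlib import Path

import yaml

from mbstrip.fixtures import _REFERENCE_ROWS

UNIPROT_FASTA = "https://rest.uniprot.org/uniprotkb/{acc}.fasta"


def fetch(accession: str) -> str:
    # accessions like B7U9B5.3 carry a sequence version suffix UniProt ignores
    acc = accession.split(".")[0]
    with urllib.request.urlopen(UNIPROT_FASTA.format(acc=acc), timeout=30) as resp:
        return resp.read().decode()


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("-o", "--out", type=Path, required=True)
    parser.add_argument("--delay", type=float, default=0.5,
                        help="seconds between requests")
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    fasta_chunks = []
    config: dict[str, dict] = {}
    for rid, species, taxon, group, _subs in _REFERENCE_ROWS:
        print(f"fetching {rid} ({species}) ...")
        raw = fetch(rid)
        header, *seq_lines = raw.strip().splitlines()
        # re-head with the panel id so FASTA and config join cleanly;
        # strip any initiator Met to stay on mature-protein numbering
        seq = "".join(seq_lines)
        if seq.startswith("M"):
            seq = seq[1:]
        fasta_chunks.append(f">{rid} {species}\n{seq}")
        config[rid] = {"species": species, "group": group, "taxon": taxon}
        time.sleep(args.delay)

    (args.out / "panel.fasta").write_text("\n".join(fasta_chunks) + "\n")
    (args.out / "panel.yaml").write_text(
        yaml.safe_dump({"name": "reference-panel-accessions", "records": config},
                       sort_keys=False)
    )
    print(f"wrote {args.out / 'panel.fasta'} and {args.out / 'panel.yaml'}")


if __name__ == "__main__":
    main()
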