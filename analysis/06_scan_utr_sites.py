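#!/usr/bin/env python
"""Scan the planted 3'UTR for seed sites and verify the deletion designs.

Reads results/data/utr.fasta, reports every canonical seed match for the
query miR, then re-scans after excising one or both sites — the in-silico
analogue of single- and double-deletion reporter constructs.
"""

import argparse
from pathlib import Path

from mirhts import io
from mirhts.target_filter import apply_site_deletion, find_seed_sites, sites_to_frame

MIR_SEQ = "UGAUUGGUACGUCUGUGGGUAG"  # synthetic mature-miR stand-in


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--mir-seq", default=MIR_SEQ)
    args = ap.parse_args()

    (record,) = io.read_fasta(args.data / "utr.fasta")
    utr = str(record.seq)
    sites = find_seed_sites(utr, args.mir_seq, mir_id="query-miR")
    io.write_table(sites_to_frame(sites, gene=record.id), args.out / "seed_sites.tsv")
    print(f"{record.id} ({len(utr)} nt): {len(sites)} seed sites")
    for s in sites:
        print(f"  {s.site_class} at {s.start}-{s.end}")

    for i, site in enumerate(sites, start=1):
        remaining = find_seed_sites(apply_site_deletion(utr, site), args.mir_seq)
        print(f"  delta{i} (delete {site.start}-{site.end}): {len(remaining)} site(s) remain")
    seq = utr
    for site in sorted(sites, key=lambda s: -s.start):
        seq = apply_site_deletion(seq, site)
    print(f"  delta-all: {len(find_seed_sites(seq, args.mir_seq))} site(s) remain")


if __name__ == "__main__":
    main()
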