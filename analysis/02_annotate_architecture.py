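#!/usr/bin/env python
"""Detect direct-repeat pairs and segment every allele into its cassette
architecture (TRD slots, central region, repeat copies).

Reads the families from 01, writes architectures.gff3 and architecture.tsv
per scenario, and prints the recovered repeat classes and TRD counts.
"""

from pathlib import Path

import pandas as pd

from domo.architecture import count_central_copies, infer_family_architectures
from domo.io import read_fasta, write_gff3

SIM = Path(__file__).resolve().parents[1] / "results" / "analysis" / "sim"


def main() -> None:
    for scen_dir in sorted(p for p in SIM.iterdir() if p.is_dir()):
        records = read_fasta(scen_dir / "family.fa")
        architectures, consensus, failures = infer_family_architectures(records)
        write_gff3(
            list(architectures.values()), records, scen_dir / "architectures.gff3"
        )
        rows = []
        for seq_id, arch in sorted(architectures.items()):
            rows.append(
                {
                    "seq_id": seq_id,
                    "n_trds": arch.n_trds,
                    "slots": ";".join(f"{s}-{e}" for s, e in arch.trd_slots),
                    "central_copies": (
                        count_central_copies(arch)
                        if arch.central_interval is not None
                        else ""
                    ),
                }
            )
        pd.DataFrame(rows).to_csv(scen_dir / "architecture.tsv", sep="\t", index=False)
        counts = pd.Series([a.n_trds for a in architectures.values()]).value_counts()
        repeat_lens = {cls: len(seq) for cls, seq in consensus.items()}
        print(
            f"{scen_dir.name}: repeat classes {repeat_lens}; "
            f"TRD counts {dict(counts.sort_index())}; "
            f"{len(failures)} unsegmented"
        )
        for seq_id, note in failures.items():
            print(f"  ! {note}")


if __name__ == "__main__":
    main()
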