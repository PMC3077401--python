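#!/usr/bin/env python
"""Assign homology labels (a, b, c, ...) to TRD instances and build the
label-position matrix — the table whose cross-position entries are the
domain-movement signature.

Writes clusters.tsv and matrix.tsv per scenario and prints each matrix.
"""

from pathlib import Path

import pandas as pd

from domo.architecture import extract_trd_instances, infer_family_architectures
from domo.clustering import cluster_trds, label_of, label_position_matrix
from domo.io import read_fasta

SIM = Path(__file__).resolve().parents[1] / "results" / "analysis" / "sim"


def main() -> None:
    for scen_dir in sorted(p for p in SIM.iterdir() if p.is_dir()):
        records = read_fasta(scen_dir / "family.fa")
        architectures, _consensus, _failures = infer_family_architectures(records)
        instances, excluded = extract_trd_instances(records, architectures)
        clusters = cluster_trds(instances)
        labels = label_of(clusters)
        pd.DataFrame(
            [
                {
                    "seq_id": t.seq_id,
                    "locus": t.locus_id,
                    "position": t.position_index,
                    "label": labels[t.key],
                }
                for t in instances
            ]
        ).to_csv(scen_dir / "clusters.tsv", sep="\t", index=False)
        loci = {r.seq_id: r.locus_id for r in records}
        matrix = label_position_matrix(clusters, list(architectures.values()), loci)
        matrix.to_csv(scen_dir / "matrix.tsv", sep="\t")
        cross = sorted(
            {
                lab
                for (sid, pos), lab in labels.items()
                if any(
                    lab == labels[key] and key[1] != pos
                    for key in labels
                )
            }
        )
        print(f"{scen_dir.name}: {len(clusters)} domain labels; "
              f"cross-position labels: {cross or 'none'}")
        print(matrix.to_string(), "\n")


if __name__ == "__main__":
    main()
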