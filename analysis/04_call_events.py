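#!/usr/bin/env python
"""Call recombination event classes from the label-position matrices and
score them against the simulation ground truth.

Writes events.tsv and metrics.json per scenario; prints per-type
precision/recall.
"""

import json
from pathlib import Path

from domo.architecture import extract_trd_instances, infer_family_architectures
from domo.clustering import cluster_trds, label_position_matrix
from domo.events import call_events, evaluate_calls
from domo.io import read_fasta, read_truth_json, write_events_tsv

SIM = Path(__file__).resolve().parents[1] / "results" / "analysis" / "sim"


def main() -> None:
    for scen_dir in sorted(p for p in SIM.iterdir() if p.is_dir()):
        records = read_fasta(scen_dir / "family.fa")
        truth = read_truth_json(scen_dir / "truth.json")
        architectures, _c, _f = infer_family_architectures(records)
        instances, _ = extract_trd_instances(records, architectures)
        clusters = cluster_trds(instances)
        loci = {r.seq_id: r.locus_id for r in records}
        matrix = label_position_matrix(clusters, list(architectures.values()), loci)
        calls = call_events(matrix, architectures)
        write_events_tsv(calls, scen_dir / "events.tsv")
        metrics = evaluate_calls(calls, truth)
        with open(scen_dir / "metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=1, sort_keys=True)
        print(f"{scen_dir.name}:")
        for call in calls:
            print(f"  {call.type} @ {call.locus_id}: {call.confidence_note}")
        for etype, m in sorted(metrics.items()):
            if m["n_truth"] or m["n_calls"]:
                print(
                    f"    {etype}: precision={m['precision']} recall={m['recall']}"
                    f" (truth {m['n_truth']}, calls {m['n_calls']})"
                )


if __name__ == "__main__":
    main()
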