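#!/usr/bin/env python
"""Aggregate the per-scenario results into one markdown summary with
ASCII architecture diagrams (results/analysis/summary.md)."""

import json
from pathlib import Path

from domo.architecture import extract_trd_instances, infer_family_architectures
from domo.clustering import cluster_trds, label_of
from domo.io import read_events_tsv, read_fasta
from domo.report import render_architecture_diagram

BASE = Path(__file__).resolve().parents[1] / "results" / "analysis"
SIM = BASE / "sim"


def main() -> None:
    lines = ["# Simulated S-gene family analysis: summary", ""]
    for scen_dir in sorted(p for p in SIM.iterdir() if p.is_dir()):
        records = read_fasta(scen_dir / "family.fa")
        architectures, _c, _f = infer_family_architectures(records)
        instances, _ = extract_trd_instances(records, architectures)
        labels = label_of(cluster_trds(instances))
        loci = {r.seq_id: r.locus_id for r in records}
        lines += [f"## {scen_dir.name}", "", "```"]
        lines += [render_architecture_diagram(architectures, labels, loci), "```", ""]
        calls = read_events_tsv(scen_dir / "events.tsv")
        lines += ["Event calls:", ""]
        lines += [f"- {c.type} @ {c.locus_id}: {c.confidence_note}" for c in calls] or ["- none"]
        metrics = json.loads((scen_dir / "metrics.json").read_text())
        recovered = [
            f"{etype} {m['recall']:.0%}"
            for etype, m in sorted(metrics.items())
            if m["n_truth"]
        ]
        lines += ["", f"Recovery vs truth: {', '.join(recovered) or 'no events injected'}", ""]
    out = BASE / "summary.md"
    out.write_text("\n".join(lines) + "\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
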