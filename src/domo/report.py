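"""Pipeline orchestration: simulate/load -> annotate -> cluster -> call ->
trees -> report.

``run_pipeline`` drives the whole analysis on a config mapping and leaves a
self-describing run directory:

    family.fa          input alleles (copied or simulated)
    truth.json         simulation ground truth (simulated runs only)
    architectures.gff3 repeat and slot annotations
    architecture.tsv   per-allele summary (n_trds, slots, central copies)
    clusters.tsv       domain label per TRD instance
    matrix.tsv         label-position matrix (alleles x slots)
    events.tsv         event calls
    trees/<locus>.nwk  per-locus NJ trees with |pos annotations
    mixing_scores.tsv  per-locus parsimony mixing score
    report.md          human-readable summary with architecture diagrams
    MANIFEST.json      stage status (failures leave partial outputs behind)

All outputs are pure functions of the config (no timestamps), so a rerun
with the same config is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import io as dio
from .architecture import count_central_copies, extract_trd_instances, infer_family_architectures
from .clustering import cluster_trds, clustering_diagnostic, label_of, label_position_matrix
from .events import call_events, evaluate_calls
from .model import DomoError, GeneArchitecture
from .simulate import SimParams, simulate_family
from .trees import build_nj_tree, position_mixing_score


# Family annotation bootstraps repeat consensus at zero mismatch tolerance:
# repeat copies are recombination substrates and near-identical, and a
# nonzero budget lets maximal windows absorb context bases. Raise
# max_mismatch_frac only for decayed input.
DEFAULTS = {
    "min_repeat_len": 12,
    "max_mismatch_frac": 0.0,
    "min_separation": 50,
    "cluster_threshold": 0.8,
    "word_size": 10,
}


def render_architecture_diagram(
    architectures: dict[str, GeneArchitecture],
    labels: dict[tuple[str, int], str],
    loci: dict[str, str],
) -> str:
    """ASCII rows mirroring the figure layout: repeat glyphs, [label] boxes
    and the central copy count, one allele per row, e.g. ``x[a]y(3)x[i]y``."""
    rows = []
    for seq_id in sorted(architectures):
        arch = architectures[seq_id]
        copies_by_pos = {}
        for copy in arch.repeat_copies:
            copies_by_pos[copy.start] = copy.class_name.lower()
        marks = []
        for copy in sorted(arch.repeat_copies, key=lambda c: c.start):
            marks.append((copy.start, copy.class_name.lower()))
        for pos, (s, e) in enumerate(arch.trd_slots, start=1):
            marks.append((s, f"[{labels.get((seq_id, pos), '?')}]"))
        if arch.central_interval is not None:
            n = count_central_copies(arch)
            marks.append((arch.central_interval[0], f"({n})"))
        glyphs = "".join(g for _, g in sorted(marks))
        rows.append(f"{seq_id}/{loci.get(seq_id, 'NA')}  {glyphs}")
    return "\n".join(rows)


def run_pipeline(config: dict, out_dir) -> Path:
    """Run the full analysis; returns the run directory.

    ``config`` holds either ``{"sim_params": {...}}`` (simulate) or
    ``{"fasta": path}`` (load), plus optional detector overrides matching
    :data:`DEFAULTS`. Stage failures raise after writing a MANIFEST that
    names the failed stage; completed outputs are left in place.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    opts = {**DEFAULTS, **{k: v for k, v in config.items() if k in DEFAULTS}}
    manifest: dict = {"config": config, "options": opts, "stages": {}}
    stage = "input"
    try:
        truth = None
        if "sim_params" in config:
            params = SimParams.from_json(config["sim_params"])
            records, truth = simulate_family(params)
            dio.write_fasta(records, out / "family.fa")
            dio.write_truth_json(truth, out / "truth.json")
        elif "fasta" in config:
            records = dio.read_fasta(config["fasta"])
            dio.write_fasta(records, out / "family.fa")
        else:
            raise DomoError("config needs either 'sim_params' or 'fasta'")
        manifest["stages"][stage] = "ok"

        stage = "architecture"
        architectures, consensus, failures = infer_family_architectures(
            records,
            min_len=opts["min_repeat_len"],
            max_mismatch_frac=opts["max_mismatch_frac"],
            min_separation=opts["min_separation"],
        )
        dio.write_gff3(list(architectures.values()), records, out / "architectures.gff3")
        arch_rows = []
        for seq_id, arch in sorted(architectures.items()):
            arch_rows.append(
                {
                    "seq_id": seq_id,
                    "n_trds": arch.n_trds,
                    "slots": ";".join(f"{s}-{e}" for s, e in arch.trd_slots),
                    "central_copies": (
                        count_central_copies(arch)
                        if arch.central_interval is not None
                        else ""
                    ),
                    "central_unit": (
                        arch.central.unit_sequence if arch.central is not None else ""
                    ),
                }
            )
        pd.DataFrame(arch_rows).to_csv(out / "architecture.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "ok": len(architectures),
            "failed": failures,
            "consensus_repeats": consensus,
        }

        stage = "clustering"
        instances, excluded = extract_trd_instances(records, architectures)
        clusters = cluster_trds(instances, threshold=opts["cluster_threshold"])
        labels = label_of(clusters)
        cluster_rows = [
            {
                "seq_id": t.seq_id,
                "locus": t.locus_id,
                "position": t.position_index,
                "label": labels[t.key],
                "length": len(t.sequence),
            }
            for t in instances
        ]
        pd.DataFrame(cluster_rows).to_csv(out / "clusters.tsv", sep="\t", index=False)
        loci = {r.seq_id: r.locus_id for r in records}
        matrix = label_position_matrix(clusters, list(architectures.values()), loci)
        matrix.to_csv(out / "matrix.tsv", sep="\t")
        manifest["stages"][stage] = {
            "n_clusters": len(clusters),
            "excluded_partial": excluded,
            **clustering_diagnostic(clusters),
        }

        stage = "events"
        calls = call_events(matrix, architectures)
        dio.write_events_tsv(calls, out / "events.tsv")
        metrics = None
        if truth is not None:
            metrics = evaluate_calls(calls, truth)
            with open(out / "metrics.json", "w") as fh:
                json.dump(metrics, fh, indent=1, sort_keys=True)
        manifest["stages"][stage] = {"n_calls": len(calls)}

        stage = "trees"
        (out / "trees").mkdir(exist_ok=True)
        scores = []
        for locus in sorted(set(loci.values())):
            locus_inst = [t for t in instances if t.locus_id == locus]
            if len(locus_inst) < 3 or len({t.position_index for t in locus_inst}) < 2:
                scores.append({"locus": locus, "n_leaves": len(locus_inst), "mixing_score": ""})
                continue
            tree = build_nj_tree(locus_inst)
            with open(out / "trees" / f"{locus}.nwk", "w") as fh:
                fh.write(tree.to_newick() + "\n")
            scores.append(
                {
                    "locus": locus,
                    "n_leaves": len(locus_inst),
                    "mixing_score": position_mixing_score(tree),
                }
            )
        pd.DataFrame(scores).to_csv(out / "mixing_scores.tsv", sep="\t", index=False)
        manifest["stages"][stage] = "ok"

        stage = "report"
        diagram = render_architecture_diagram(architectures, labels, loci)
        lines = [
            "# S-gene domain-movement run report",
            "",
            "## Options",
            "",
        ]
        lines += [f"- {k} = {v}" for k, v in sorted(opts.items())]
        lines += ["", "## Architectures", "", "```", diagram, "```", ""]
        lines += ["## Event calls", ""]
        for call in calls:
            lines.append(f"- {call.type} @ {call.locus_id}: {call.confidence_note}")
        if not calls:
            lines.append("- none")
        lines += ["", "## Position mixing", ""]
        for row in scores:
            lines.append(
                f"- {row['locus']}: score {row['mixing_score']} over {row['n_leaves']} TRDs"
                + (
                    " (separated)"
                    if row["mixing_score"] == 1
                    else " (mixed)" if row["mixing_score"] != "" else ""
                )
            )
        if metrics is not None:
            lines += ["", "## Recovery vs simulation truth", ""]
            for etype, m in sorted(metrics.items()):
                lines.append(
                    f"- {etype}: precision={m['precision']} recall={m['recall']} "
                    f"(truth n={m['n_truth']}, calls n={m['n_calls']})"
                )
        with open(out / "report.md", "w") as fh:
            fh.write("\n".join(lines) + "\n")
        manifest["stages"][stage] = "ok"
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = f"failed at stage {stage}: {exc}"
        with open(out / "MANIFEST.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
        raise
    with open(out / "MANIFEST.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return out
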