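#!/usr/bin/env python
"""Build per-locus NJ trees of TRD instances and score position mixing.

A parsimony score of 1 means TRD1 and TRD2 sequences fall into two clean
clades (the no-movement pattern); >= 2 means domains have moved between
positions. Writes trees/<locus>.nwk and mixing_scores.tsv per scenario.
"""

from pathlib import Path

import pandas as pd

from domo.architecture import extract_trd_instances, infer_family_architectures
from domo.io import read_fasta
from domo.trees import build_nj_tree, position_mixing_score

SIM = Path(__file__).resolve().parents[1] / "results" / "analysis" / "sim"


def main() -> None:
    for scen_dir in sorted(p for p in SIM.iterdir() if p.is_dir()):
        records = read_fasta(scen_dir / "family.fa")
        architectures, _c, _f = infer_family_architectures(records)
        instances, _ = extract_trd_instances(records, architectures)
        (scen_dir / "trees").mkdir(exist_ok=True)
        rows = []
        for locus in sorted({t.locus_id for t in instances}):
            sub = [t for t in instances if t.locus_id == locus]
            if len(sub) < 3 or len({t.position_index for t in sub}) < 2:
                rows.append({"locus": locus, "n_leaves": len(sub), "score": ""})
                continue
            tree = build_nj_tree(sub)
            (scen_dir / "trees" / f"{locus}.nwk").write_text(tree.to_newick() + "\n")
            score = position_mixing_score(tree)
            rows.append({"locus": locus, "n_leaves": len(sub), "score": score})
        pd.DataFrame(rows).to_csv(scen_dir / "mixing_scores.tsv", sep="\t", index=False)
        verdicts = ", ".join(
            f"{r['locus']}: score {r['score']}"
            + (" (separated)" if r["score"] == 1 else " (mixed)" if r["score"] != "" else "")
            for r in rows
        )
        print(f"{scen_dir.name}: {verdicts}")


if __name__ == "__main__":
    main()
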