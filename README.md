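# domo

Detection and simulation of **domain movement** in the specificity (S)
genes of Type I and Type IIG restriction–modification systems.

## The problem

The S subunit of a Type I RM system recognizes an asymmetric bipartite DNA
target (e.g. `GAA(N)6RTCG`) through two target recognition domains: TRD1
reads the 5′ half, TRD2 the 3′ half. In several bacterial S-gene families
the TRDs are embedded between short direct repeats,

```
flank – x – TRD1 – y – central – x – TRD2 – y – flank
```

with repeat classes of characteristic length (x 37 bp / y 49 bp in one
family; x′ 27 / y′ 53 / z′ 14 bp in another; x″ 21 / y″ 19 bp in a Type IIG
family) and a central tandem repeat (12-bp unit `CACAGAATTAAA`, 2–6 copies,
or a 24-bp unit `CAGTGTCGGCTCGCCGAACTTGAG`, 0–4 copies) whose copy number
sets the spacer length of the recognition site — for EcoR124I, going from 2
to 3 central copies turns `GAA(N)6RTCG` into `GAA(N)7RTCG`.

Recombination at these repeats lets a domain *move between positions*: the
same sequence can appear at TRD1 in one allele and TRD2 in another allele
of the same locus. The same mechanism explains alleles collapsed to one TRD
(x-by-x recombination), expanded to three TRDs (TRD1-TRD2-TRD2 via the z
repeats), central-copy-number changes, and domain sharing between loci.
Because each TRD reads one half-site, every such event rewires sequence
specificity — a distinct route to protein diversification.

This package provides, from nucleotide sequence alone:

- **repeat detection** — maximal direct-repeat pairs (Hamming model,
  seed-and-extend, oracle-verified) and central tandem repeats;
- **architecture inference** — segmentation of each allele into TRD slots,
  central region and repeat copies, for 1/2/3-TRD layouts;
- **domain clustering** — homology labels (a, b, c, …) over TRD instances
  via single-linkage on global-alignment identity (threshold 0.8);
- **event calling** — SUBSTITUTION, MOVEMENT, DELETION, DUPLICATION,
  CENTRAL_COPY_CHANGE and INTER_LOCUS_SHARING from the label–position
  matrix, plus the EcoR124I-style linear spacer model;
- **tree mixing statistic** — neighbor-joining trees of TRD instances
  scored by small parsimony over position states: score 1 ⇔ TRD1/TRD2
  separate cleanly (no movement), ≥ 2 ⇔ positions mix;
- **dotplot screen** — cross-slot exact-match segments between alleles as
  movement candidates;
- **a forward simulator** — S-gene families evolving under all six event
  types with a byte-replayable ground-truth log, used for
  parameter-recovery validation.

## Worked example

```python
from domo.simulate import SimParams, simulate_family
from domo.architecture import extract_trd_instances, infer_family_architectures
from domo.clustering import cluster_trds, label_position_matrix
from domo.events import call_events
from domo.trees import build_nj_tree, position_mixing_score

params = SimParams(event_counts={"MOVEMENT": 1, "SUBSTITUTION": 1}, seed=42)
records, truth = simulate_family(params)

architectures, consensus, _ = infer_family_architectures(records)
instances, _ = extract_trd_instances(records, architectures)
clusters = cluster_trds(instances)
loci = {r.seq_id: r.locus_id for r in records}
matrix = label_position_matrix(clusters, list(architectures.values()), loci)
for call in call_events(matrix, architectures):
    print(f"{call.type} @ {call.locus_id}: {call.confidence_note}")
for locus in ("L1", "L2"):
    sub = [t for t in instances if t.locus_id == locus]
    print(locus, "mixing score:", position_mixing_score(build_nj_tree(sub)))
```

prints

```
MOVEMENT @ L1: label b occupies TRD1 and TRD2 at L1
SUBSTITUTION @ L1: labels {a, e} alternate at TRD1 of L1
L1 mixing score: 2
L2 mixing score: 1
```

Reading this: at locus L1 the domain labelled *b* — ancestrally the TRD2
domain — also occupies TRD1 in one allele (the movement), and TRD1
additionally alternates between two unrelated domains (a substitution).
The NJ tree of L1's TRD instances needs 2 position-state changes (mixed),
while untouched L2 needs exactly 1 (TRD1 and TRD2 form two clean clades).
Both injected events are recovered; the event-free locus stays quiet.

The same pipeline runs from the shell:

```bash
domo simulate --out-fasta fam.fa --out-truth truth.json
domo detect fam.fa --out-prefix run1
domo evaluate --calls run1.events.tsv --truth truth.json
domo tree fam.fa --out fam.nwk --score
domo run --config config.json --out-dir rundir   # end-to-end + report.md
```

## Analysis scripts

`analysis/01…06` drive the full study on simulated families
(substitution-only baseline, two-locus movement, structural
duplication/deletion, single-locus Type IIG movement), writing FASTA/GFF3/
TSV/newick artifacts and a markdown summary under `results/analysis/`:

```bash
for s in analysis/0*.py; do python "$s"; done
```

## Limitations

Input alleles are assumed like-oriented (no reverse-complement search);
repeat mismatch handling is Hamming-only (no indels); trees are
distance-based NJ scored qualitatively, not Bayesian posteriors. See
`docs/methods.md` for the model, parameter defaults and the simulator's
scope.
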