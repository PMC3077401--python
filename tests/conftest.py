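import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracles.py

from domo.simulate import SimParams, simulate_family

ALL_EVENTS = {
    "SUBSTITUTION": 1,
    "MOVEMENT": 1,
    "DELETION": 1,
    "DUPLICATION": 1,
    "CENTRAL_COPY_CHANGE": 1,
    "INTER_LOCUS_SHARING": 1,
}


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture(scope="session")
def all_events_family():
    """One family with every event type injected once, zero noise."""
    params = SimParams(event_counts=dict(ALL_EVENTS), seed=11)
    records, truth = simulate_family(params)
    return params, records, truth


@pytest.fixture(scope="session")
def annotated_family(all_events_family):
    """The same family run through annotation, clustering and the matrix."""
    from domo.architecture import extract_trd_instances, infer_family_architectures
    from domo.clustering import cluster_trds, label_position_matrix

    _params, records, truth = all_events_family
    architectures, consensus, failures = infer_family_architectures(records)
    assert not failures
    instances, _excluded = extract_trd_instances(records, architectures)
    clusters = cluster_trds(instances)
    loci = {r.seq_id: r.locus_id for r in records}
    matrix = label_position_matrix(clusters, list(architectures.values()), loci)
    return records, truth, architectures, instances, clusters, matrix
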