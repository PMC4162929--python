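import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from cspdetect.cluster_filters import heterozygosity_measures
from cspdetect.csp import CspParams, csp_score, detect_cf_candidates
from cspdetect.phasing import CandidatePairSet, EmPhasingBackend
from cspdetect.synthetic import clusters_to_fragments, preset_params, simulate
from cspdetect.truth_labels import TruthParams, label_fragments


class SingleCertainPairBackend:
    """Candidate pairs: hapA all-zeros, hapB all-ones, probability 1."""

    def pairs_for(self, window_sites):
        w = len(window_sites)
        return CandidatePairSet(
            window_sites=tuple(window_sites),
            pairs=[((0,) * w, (1,) * w, 1.0)],
        )


@pytest.fixture
def certain_pair_backend():
    return SingleCertainPairBackend()


@pytest.fixture
def certain_pair_5():
    return CandidatePairSet(
        window_sites=(1, 2, 3, 4, 5),
        pairs=[((0, 0, 0, 0, 0), (1, 1, 1, 1, 1), 1.0)],
    )


def run_duitama_pipeline(seed: int) -> dict:
    """Full chimera-detection pipeline on one duitama-like simulation."""
    params = preset_params("duitama-like", seed=seed)
    panel, clusters, sim_truth = simulate(params)
    fragments = clusters_to_fragments(clusters)
    trio = sim_truth.as_trio_truth()
    labels = label_fragments(fragments, trio, TruthParams())
    backend = EmPhasingBackend(panel)
    csp_params = CspParams()
    results = [csp_score(f, backend, csp_params) for f in fragments]
    candidates = detect_cf_candidates(results, csp_params.threshold)
    by_cluster = {c.id: c for c in clusters}
    lengths, het_totals = [], []
    for frag in fragments:
        cl = by_cluster[frag.source_cluster]
        lengths.append(float(cl.length))
        try:
            het_totals.append(float(heterozygosity_measures(cl).total))
        except Exception:
            het_totals.append(None)
    return {
        "panel": panel,
        "clusters": clusters,
        "fragments": fragments,
        "truth": trio,
        "labels": [l.label for l in labels],
        "csp_scores": [r.score for r in results],
        "candidates": candidates,
        "cluster_lengths": lengths,
        "het_totals": het_totals,
    }


@pytest.fixture(scope="session")
def duitama_runs():
    """Five seeds of the duitama-like pipeline (shared: it is the slow part)."""
    return [run_duitama_pipeline(seed) for seed in range(5)]
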