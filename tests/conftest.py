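import numpy as np
import pytest

from cegcn.cohort import DiseaseCatalog, GraphSnapshot, SnapshotSequence


@pytest.fixture(scope="session")
def catalog4():
    return DiseaseCatalog(("d0", "d1", "d2", "d3"))


@pytest.fixture(scope="session")
def catalog14():
    return DiseaseCatalog(tuple(f"disease_{i:02d}" for i in range(14)))


def sequence_from_adjacencies(adjs, age_min):
    """Build a SnapshotSequence directly from binary adjacency matrices."""
    snaps = [GraphSnapshot(age=age_min + k, adjacency=np.asarray(a, dtype=np.int64),
                           weights=np.asarray(a, dtype=np.int64))
             for k, a in enumerate(adjs)]
    return SnapshotSequence(snaps, age_min, age_min + len(adjs) - 1)


def random_adjacency(rng, n, p=0.4):
    upper = np.triu(rng.random((n, n)) < p, k=1).astype(np.int64)
    return upper + upper.T


@pytest.fixture(scope="session")
def small_planted_sequence():
    """A reduced planted-rule cohort shared by training smoke tests."""
    from cegcn.simulate import experiment_config, simulated_sequence

    cfg = experiment_config(seed=42, n_patients=200)
    sequence, cohort, truth = simulated_sequence(cfg, rule_strength=0.2)
    return sequence, cohort, truth


@pytest.fixture(scope="session")
def planted_result():
    """Five-seed paired CE-GCN vs static-GCN runs on planted-rule cohorts."""
    from cegcn.experiments import planted_experiment

    return planted_experiment(n_seeds=5, base_seed=1)


@pytest.fixture(scope="session")
def null_result():
    """Ten-seed null-calibration runs on exchangeable cohorts."""
    from cegcn.experiments import null_calibration

    return null_calibration(n_seeds=10, base_seed=1)
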