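import numpy as np
import pytest

from metabofunc.datatypes import DetectionStatus
from metabofunc.model import ModelSpec, MetaboliteFunctionModel, featurize_dataset
from metabofunc.splitting import cluster_by_output, split_clusters
from metabofunc.synthetic import FixtureSpec, generate_dataset, make_unit_fixtures


@pytest.fixture
def unit():
    return make_unit_fixtures()


@pytest.fixture(scope="session")
def small_ds():
    """~150-molecule planted-motif dataset with the default status mix."""
    return generate_dataset(FixtureSpec(n_molecules=150, seed=11))


@pytest.fixture(scope="session")
def small_split(small_ds):
    table = small_ds.truth_table()
    selected = small_ds.motif_term_ids
    clusters = cluster_by_output(table, selected)
    plan = split_clusters(clusters, 0.9, 11, table, selected)
    return table, selected, plan


@pytest.fixture(scope="session")
def small_featurized(small_ds, small_split):
    table, selected, plan = small_split
    return featurize_dataset(small_ds.records, table, selected, True, None,
                             plan.train_ids)


@pytest.fixture(scope="session")
def study_run():
    """The frozen study-scale run: planted-motif dataset (n=1000, all
    detected-and-quantified, 5% label noise), 0.9/0.1 cluster split, GAT and
    fingerprint-MLP baseline with default hyperparameters, seed 0 throughout.

    Shared by the learnability and attention-enrichment tests so the GAT is
    trained once.
    """
    ds = generate_dataset(FixtureSpec(
        n_molecules=1000, seed=0,
        status_mix={DetectionStatus.detected_quantified: 1.0}))
    table = ds.truth_table()
    selected = ds.motif_term_ids
    clusters = cluster_by_output(table, selected)
    plan = split_clusters(clusters, 0.9, 0, table, selected)
    fd = featurize_dataset(ds.records, table, selected, True, None, plan.train_ids)
    train = fd.subset(plan.train_ids)
    test = fd.subset(plan.test_ids)
    gat = MetaboliteFunctionModel(
        train, ModelSpec(arch="gat", n_labels=len(selected), seed=0)).fit()
    baseline = MetaboliteFunctionModel(
        train, ModelSpec(arch="mlp_fp", n_labels=len(selected), seed=0)).fit()
    return {"ds": ds, "train": train, "test": test, "gat": gat,
            "baseline": baseline, "selected": selected}


def rng_for(name: str) -> np.random.Generator:
    """Stable per-test rng so tests stay independent of execution order."""
    import zlib

    return np.random.default_rng(zlib.crc32(name.encode()) % (2**31))
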