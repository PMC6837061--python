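"""Semi-supervised embedding: objective, training, frozen-core contract."""

import numpy as np
import pytest

from molbayes.bayes import Prior, TrainConfig, train_map
from molbayes.molgraph import parse_smiles
from molbayes.mpnn import MPNNConfig
from molbayes.semisup import (
    SemiSupReadoutModel,
    SemiSupTrainConfig,
    _batch_objective,
    embed_molecule,
    semisup_objective,
    train_semisupervised,
)


@pytest.fixture(scope="module")
def trained_embedding(small_library, tiny_config):
    graphs, _ = small_library
    return train_semisupervised(
        graphs,
        tiny_config,
        SemiSupTrainConfig(epochs=6, batch_size=8, lr=0.02, seed=1),
    )


def test_objective_smallest_case(tiny_config):
    """Single single-atom molecule, one negative sample: finite objective."""
    graphs = [parse_smiles("C"), parse_smiles("O")]
    model = train_semisupervised(
        graphs, tiny_config, SemiSupTrainConfig(epochs=1, batch_size=2, n_negatives=1, seed=0)
    )
    obj = semisup_objective([graphs[0]], model, np.random.default_rng(0))
    assert np.isfinite(obj)


def test_objective_requires_registered_molecule(trained_embedding):
    with pytest.raises(KeyError, match="not registered"):
        semisup_objective(
            [parse_smiles("ClCCl")], trained_embedding, np.random.default_rng(0)
        )


def test_duplicated_molecule_shares_identifier_and_contribution(tiny_config):
    """Copies of one molecule tie their identifier, so per-copy objective
    contributions are identical."""
    graphs = [parse_smiles("CCO"), parse_smiles("CCO"), parse_smiles("CCC")]
    model = train_semisupervised(
        graphs, tiny_config, SemiSupTrainConfig(epochs=2, batch_size=3, seed=0)
    )
    assert len(model.mol_keys) == 2  # duplicates collapse
    a = semisup_objective([graphs[0]], model, np.random.default_rng(5))
    b = semisup_objective([graphs[1]], model, np.random.default_rng(5))
    assert a == b


def test_objective_matches_bruteforce_oracle_sharing_rng(trained_embedding, small_library):
    """Negative-sampling objective against a naive per-atom re-implementation
    drawing the same negatives from the same generator state."""
    graphs, _ = small_library
    batch = graphs[:4]
    model = trained_embedding
    k = model.n_negatives
    got = semisup_objective(batch, model, np.random.default_rng(33))

    params = model.params()
    config = model.config
    T = config.steps
    # naive: recompute everything molecule-by-molecule, atom-by-atom
    from molbayes.mpnn import forward_hidden

    h_all, owners = [], []
    for gi, g in enumerate(batch):
        hs, _ = forward_hidden(g, params, config)
        for v in range(g.n_atoms):
            h_all.append(hs[T][v])
            owners.append((gi, v))
    h_all = np.array(h_all)
    n_pool = len(h_all)
    rng = np.random.default_rng(33)
    negs = rng.integers(0, n_pool, size=(n_pool, k))

    def logsig(v):
        return -np.logaddexp(0.0, -v)

    expected = 0.0
    for i, (gi, v) in enumerate(owners):
        g = batch[gi]
        hs, _ = forward_hidden(g, params, config)
        nb = np.zeros(config.hidden)
        for w in g.neighbors(v):
            nb += hs[T][w]
        ctx = params["u"][model.mol_index(g)] + params["Q"] @ nb
        o_self = params["P"] @ hs[T][v]
        expected += logsig(ctx @ o_self)
        for j in negs[i]:
            expected += logsig(-(ctx @ (params["P"] @ h_all[j])))
    assert got == pytest.approx(expected, rel=1e-12)


def test_training_improves_objective_and_is_deterministic(small_library, tiny_config):
    graphs, _ = small_library
    cfg = SemiSupTrainConfig(epochs=6, batch_size=8, lr=0.02, seed=2)
    a = train_semisupervised(graphs, tiny_config, cfg)
    b = train_semisupervised(graphs, tiny_config, cfg)
    np.testing.assert_array_equal(a.vec, b.vec)
    assert a.objective_trace[-1] > a.objective_trace[0]


def test_training_requires_two_molecules(tiny_config):
    with pytest.raises(ValueError, match="two"):
        train_semisupervised([parse_smiles("C")], tiny_config)


def test_embed_molecule_contracts(trained_embedding, small_library):
    graphs, _ = small_library
    # re-embedding a training molecule is identical
    a = embed_molecule(graphs[0], trained_embedding)
    b = embed_molecule(graphs[0], trained_embedding)
    for x, y in zip(a.states, b.states):
        np.testing.assert_array_equal(x, y)
    # unseen molecule: valid states, no identifier needed
    unseen = embed_molecule(parse_smiles("CCOC(=O)C"), trained_embedding)
    assert all(np.isfinite(h).all() for h in unseen.states)
    # isolated atom goes through the degree-0 path
    single = embed_molecule(parse_smiles("C"), trained_embedding)
    assert single.states[-1].shape[0] == 1


def test_similar_molecules_embed_closer_than_dissimilar(tiny_config):
    """Repeated-scaffold fixture: cosine similarity of mean atom states is
    higher for two same-scaffold molecules than for a cross-scaffold pair."""
    benzenes = ["Cc1ccccc1", "CCc1ccccc1", "OCc1ccccc1", "Nc1ccccc1"]
    chains = ["CCCCC", "CCCCCC", "CCCCO", "CCCCN"]
    graphs = [parse_smiles(s) for s in benzenes + chains]
    model = train_semisupervised(
        graphs, tiny_config, SemiSupTrainConfig(epochs=25, batch_size=4, lr=0.02, seed=3)
    )

    def mean_state(g):
        return embed_molecule(g, model).states[-1].mean(axis=0)

    def cos(a, b):
        return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))

    same = cos(mean_state(graphs[0]), mean_state(graphs[1]))
    cross = cos(mean_state(graphs[0]), mean_state(graphs[4]))
    assert same > cross


def test_frozen_core_contract(trained_embedding, small_library):
    """Supervised training on top never touches the embedding parameters."""
    graphs, table = small_library
    before = trained_embedding.vec.copy()
    model = SemiSupReadoutModel(trained_embedding)
    train_map(
        model,
        graphs,
        table["y"].to_numpy(),
        Prior(1.0),
        TrainConfig(epochs=15, lr=1e-2, seed=0),
    )
    np.testing.assert_array_equal(trained_embedding.vec, before)


def test_readout_model_feature_schema_mismatch(trained_embedding):
    from molbayes.molgraph import parse_smiles as ps

    wide = ps("CCO", elements=("C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "B"))
    with pytest.raises(ValueError, match="schema"):
        embed_molecule(wide, trained_embedding)


def test_semisupervised_beats_supervised_in_low_data_regime():
    """30 labelled + 500 unlabelled molecules: mean test RMSE over 10 seeds
    is lower for the semi-supervised model than for the fully supervised
    one — the low-data motivation for learning descriptors from structures."""
    from molbayes.estimators import GraphConvUncertaintyRegressor, pretrain_embedding
    from molbayes.synthetic import make_labelled_dataset

    semi_rmse, full_rmse = [], []
    for seed in range(10):
        graphs, table = make_labelled_dataset(630, seed=seed)
        y = table["y"].to_numpy()
        labelled = list(range(30))
        unlabelled = list(range(30, 530))
        test = list(range(530, 630))
        g_test = [graphs[i] for i in test]
        config = MPNNConfig(steps=2, hidden=12, fingerprint=24, head_hidden=(16, 16))
        emb = pretrain_embedding(
            [graphs[i] for i in labelled + unlabelled], config,
            SemiSupTrainConfig(seed=seed, epochs=8, lr=5e-3),
        )
        semi = GraphConvUncertaintyRegressor(
            steps=2, hidden=12, fingerprint=24, head_hidden=(16, 16),
            representation="semisupervised", inference="map",
            epochs=150, warmup_epochs=300, warmup_lr=5e-3, learning_rate=1e-3,
            batch_size=16, prior_scale=10.0, random_state=seed,
        )
        semi.fit([graphs[i] for i in labelled], y[labelled], embedding=emb)
        semi_rmse.append(np.sqrt(np.mean((semi.predict(g_test) - y[test]) ** 2)))
        full = GraphConvUncertaintyRegressor(
            steps=2, hidden=12, fingerprint=24, head_hidden=(16, 16),
            inference="map", epochs=60, warmup_epochs=100, warmup_lr=3e-3,
            learning_rate=1e-3, batch_size=16, random_state=seed,
        )
        full.fit([graphs[i] for i in labelled], y[labelled])
        full_rmse.append(np.sqrt(np.mean((full.predict(g_test) - y[test]) ** 2)))
    assert np.mean(semi_rmse) < np.mean(full_rmse)


def test_semisup_gradient_matches_finite_differences(small_library, tiny_config):
    """Analytic gradients of the negative-sampling objective (all groups)."""
    graphs, _ = small_library
    model = train_semisupervised(
        graphs[:6], tiny_config, SemiSupTrainConfig(epochs=1, batch_size=6, seed=0)
    )
    packer = model.packer
    vec = model.vec
    idx = [model.mol_index(g) for g in graphs[:6]]

    def obj(v):
        return _batch_objective(
            graphs[:6], idx, packer.unpack(v), tiny_config, 3,
            np.random.default_rng(77),
        )

    gvec = packer.zeros()
    _batch_objective(
        graphs[:6], idx, packer.unpack(vec), tiny_config, 3,
        np.random.default_rng(77), packer.unpack(gvec),
    )
    rng = np.random.default_rng(1)
    eps = 1e-6
    sample = rng.choice(packer.size, size=150, replace=False)
    for i in sample:
        vp, vm = vec.copy(), vec.copy()
        vp[i] += eps
        vm[i] -= eps
        fd = (obj(vp) - obj(vm)) / (2 * eps)
        denom = max(abs(fd), abs(gvec[i]))
        if denom > 1e-8:
            assert abs(gvec[i] - fd) / denom < 1e-4
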