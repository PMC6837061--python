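"""Unsupervised atom-environment embeddings from unlabelled structures.

The idea: persistent chemical motifs recur across molecules, so hidden
states that make each atom's environment *predictable* from its molecule
and its neighbours will cluster similar environments — no property labels
needed. Construction (a paragraph-vector-style objective with negative
sampling):

* every training molecule n gets an identifier vector u_n (a training-only
  nuisance parameter describing the molecule's "type");
* for each atom v, a context c_v = u_n + Q * sum_{w in N(v)} h_w^T is asked
  to score the atom's own environment code o_v = P * h_v^T above codes of
  negative atoms drawn from the batch, via logistic scores;
* the log-likelihood sum_v [ log s(c_v . o_v)
  + sum_{k} log s(-c_v . o_{neg_k}) ] is maximised over the message-passing
  transition matrices, Q, P, and the identifiers.

Hidden states are continuous and used directly as prediction targets
through the learned projection P (no discretisation codebook). After
training, the transition matrices are frozen; a supervised readout + head
(:class:`SemiSupReadoutModel`) is trained on top with labels, and dropout
is applied only to those top layers. Unseen molecules need no identifier:
embedding is a pure function of the frozen transition matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .molgraph import MolecularGraph
from .mpnn import (
    FlatPacker,
    HiddenStates,
    MPNNConfig,
    backward_hidden,
    forward_hidden,
    sample_masks,
)


@dataclass(frozen=True)
class SemiSupTrainConfig:
    epochs: int = 20
    batch_size: int = 32
    lr: float = 1e-3
    n_negatives: int = 5
    context_dim: int | None = None  # None => hidden width
    seed: int = 0


def _mol_key(graph: MolecularGraph) -> str:
    if graph.smiles is None:
        raise ValueError("semi-supervised training requires graphs parsed from SMILES")
    return Chem.CanonSmiles(graph.smiles)


def _embed_shapes(config: MPNNConfig, context_dim: int, n_mols: int):
    shapes = [s for s in config.param_shapes() if s[0].startswith("H")]
    shapes += [
        ("Q", (context_dim, config.hidden)),
        ("P", (context_dim, config.hidden)),
        ("u", (n_mols, context_dim)),
    ]
    return shapes


@dataclass
class SemiSupModel:
    """Frozen outcome of semi-supervised training.

    ``vec`` packs the message-passing matrices H_N^t, the context/target
    projections Q and P, and one identifier u_n per distinct training
    molecule (keyed by canonical SMILES).
    """

    config: MPNNConfig
    context_dim: int
    n_negatives: int
    vec: np.ndarray
    mol_keys: dict[str, int]
    objective_trace: list[float] = field(default_factory=list)

    @property
    def packer(self) -> FlatPacker:
        return FlatPacker(
            _embed_shapes(self.config, self.context_dim, len(self.mol_keys))
        )

    def params(self) -> dict[str, np.ndarray]:
        return self.packer.unpack(self.vec)

    def embed_params(self) -> dict[str, np.ndarray]:
        return {k: v for k, v in self.params().items() if k.startswith("H")}

    def mol_index(self, graph: MolecularGraph) -> int:
        key = _mol_key(graph)
        if key not in self.mol_keys:
            raise KeyError(f"molecule {key!r} was not registered during training")
        return self.mol_keys[key]


def _log_sigmoid(x: np.ndarray) -> np.ndarray:
    return -np.logaddexp(0.0, -x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return np.exp(_log_sigmoid(x))


def _batch_objective(
    graphs: list[MolecularGraph],
    mol_idx: list[int],
    params: dict[str, np.ndarray],
    config: MPNNConfig,
    n_negatives: int,
    rng: np.random.Generator,
    grads: dict[str, np.ndarray] | None = None,
) -> float:
    """Negative-sampling log-likelihood of one molecule batch.

    Negatives for the atoms are drawn in a fixed, documented order: atoms
    are visited in batch order, and for each atom ``n_negatives`` indices
    into the batch-wide atom pool are drawn with ``rng.integers``. A
    brute-force re-implementation sharing the same generator state
    reproduces the value exactly.
    """
    T = config.steps
    caches, h_final, nb_sums = [], [], []
    for g in graphs:
        hs, cache = forward_hidden(g, params, config)
        caches.append((g, hs, cache))
        h = hs[T]
        nb = np.zeros_like(h)
        if g.edge_src.size:
            np.add.at(nb, g.edge_dst, h[g.edge_src])
        h_final.append(h)
        nb_sums.append(nb)
    H_all = np.concatenate(h_final, axis=0)
    NB_all = np.concatenate(nb_sums, axis=0)
    owners = np.concatenate(
        [np.full(g.n_atoms, i, dtype=np.intp) for i, g in enumerate(graphs)]
    )
    u_rows = np.asarray([mol_idx[i] for i in owners])
    Q, P, U = params["Q"], params["P"], params["u"]
    CTX = U[u_rows] + NB_all @ Q.T
    O = H_all @ P.T
    n_pool = H_all.shape[0]

    negs = rng.integers(0, n_pool, size=(n_pool, n_negatives))
    s_pos = np.einsum("ij,ij->i", CTX, O)
    s_neg = np.einsum("ij,ikj->ik", CTX, O[negs])
    obj = float(_log_sigmoid(s_pos).sum() + _log_sigmoid(-s_neg).sum())

    if grads is None:
        return obj

    g_pos = 1.0 - _sigmoid(s_pos)  # d obj / d s_pos
    g_neg = -_sigmoid(s_neg)  # d obj / d s_neg
    dCTX = g_pos[:, None] * O + np.einsum("ik,ikj->ij", g_neg, O[negs])
    dO = g_pos[:, None] * CTX
    np.add.at(dO, negs.ravel(), (g_neg[:, :, None] * CTX[:, None, :]).reshape(-1, CTX.shape[1]))

    np.add.at(grads["u"], u_rows, dCTX)
    grads["Q"] += dCTX.T @ NB_all
    grads["P"] += dO.T @ H_all
    dNB = dCTX @ Q
    dH = dO @ P
    start = 0
    for (g, hs, cache), h in zip(caches, h_final):
        stop = start + g.n_atoms
        dh_T = dH[start:stop].copy()
        if g.edge_src.size:
            np.add.at(dh_T, g.edge_src, dNB[start:stop][g.edge_dst])
        d_hs: list = [None] * (T + 1)
        d_hs[T] = dh_T
        backward_hidden(g, params, config, cache, d_hs, grads)
        start = stop
    return obj


def semisup_objective(
    batch: list[MolecularGraph], model: SemiSupModel, rng: np.random.Generator
) -> float:
    """Log-likelihood of a molecule batch under the trained (or current) model."""
    if not batch:
        raise ValueError("batch must be non-empty")
    idx = [model.mol_index(g) for g in batch]
    return _batch_objective(
        batch, idx, model.params(), model.config, model.n_negatives, rng
    )


def train_semisupervised(
    molecules: list[MolecularGraph],
    config: MPNNConfig,
    train_config: SemiSupTrainConfig | None = None,
) -> SemiSupModel:
    """Stochastic gradient ascent on the negative-sampling objective.

    Duplicate molecules (same canonical SMILES) share one identifier.
    Deterministic under the configured seed; the per-epoch mean objective
    per molecule is recorded in ``objective_trace``.
    """
    if len(molecules) < 2:
        raise ValueError("need at least two molecules")
    tc = train_config or SemiSupTrainConfig()
    c_dim = tc.context_dim or config.hidden
    keys: dict[str, int] = {}
    mol_idx = []
    for g in molecules:
        key = _mol_key(g)
        if key not in keys:
            keys[key] = len(keys)
        mol_idx.append(keys[key])

    packer = FlatPacker(_embed_shapes(config, c_dim, len(keys)))
    rng = np.random.default_rng(tc.seed)
    vec = packer.zeros()
    params = packer.unpack(vec)
    for name, shape in packer.shapes:
        if name == "u":
            params[name][...] = rng.normal(0.0, 0.1, size=shape)
        else:
            params[name][...] = rng.normal(0.0, 1.0 / np.sqrt(shape[-1]), size=shape)

    from .bayes import Adam

    opt = Adam(tc.lr)
    n = len(molecules)
    trace = []
    for _epoch in range(tc.epochs):
        perm = rng.permutation(n)
        total = 0.0
        for start in range(0, n, tc.batch_size):
            sel = perm[start : start + tc.batch_size]
            gvec = packer.zeros()
            grads = packer.unpack(gvec)
            obj = _batch_objective(
                [molecules[i] for i in sel],
                [mol_idx[i] for i in sel],
                params,
                config,
                tc.n_negatives,
                rng,
                grads,
            )
            vec -= opt.step(-gvec)  # ascent
            total += obj
        trace.append(total / n)
    return SemiSupModel(
        config=config,
        context_dim=c_dim,
        n_negatives=tc.n_negatives,
        vec=vec,
        mol_keys=keys,
        objective_trace=trace,
    )


def embed_molecule(graph: MolecularGraph, model: SemiSupModel) -> HiddenStates:
    """Hidden states under the frozen transition matrices.

    Works for molecules never seen during training (no identifier is
    involved at inference). Raises on a feature-schema mismatch.
    """
    if graph.atom_features.shape[1] != model.config.atom_dim:
        raise ValueError(
            f"atom feature width {graph.atom_features.shape[1]} does not match "
            f"the training schema ({model.config.atom_dim})"
        )
    hs, _ = forward_hidden(graph, model.embed_params(), model.config)
    return HiddenStates(states=hs)


class SemiSupReadoutModel:
    """Supervised readout + head over frozen semi-supervised hidden states.

    Implements the same flat-vector Model protocol as the fully supervised
    network, but its parameter vector contains only the readout matrices
    W_t and the output head: the embedding core cannot move during
    supervised training by construction. Hidden states of repeatedly seen
    graphs are cached. Dropout masks only the layers on top of the hidden
    states (fingerprint + head).
    """

    dropout_scope = "top"

    def __init__(self, semisup: SemiSupModel, fingerprint: int | None = None,
                 head_hidden: tuple[int, int] | None = None):
        base = semisup.config
        self.config = MPNNConfig(
            steps=base.steps,
            hidden=base.hidden,
            fingerprint=fingerprint or base.fingerprint,
            head_hidden=head_hidden or base.head_hidden,
            elements=base.elements,
            bond_dim=base.bond_dim,
        )
        self.semisup = semisup
        self._embed_params = semisup.embed_params()
        shapes = [
            s for s in self.config.param_shapes() if not s[0].startswith("H")
        ]
        self.packer = FlatPacker(shapes)
        self.n_params = self.packer.size
        self._hidden_cache: dict[int, list[np.ndarray]] = {}
        self._stack_cache: dict[tuple, tuple] = {}

    def init(self, rng: np.random.Generator) -> np.ndarray:
        vec = self.packer.zeros()
        params = self.packer.unpack(vec)
        for name, shape in self.packer.shapes:
            if name.startswith("b"):
                continue
            params[name][...] = rng.normal(0.0, 1.0 / np.sqrt(shape[-1]), size=shape)
        return vec

    def sample_masks(self, rng, p):
        return sample_masks(self.config, rng, p, scope=self.dropout_scope)

    def hidden(self, graph: MolecularGraph) -> list[np.ndarray]:
        key = id(graph)
        if key not in self._hidden_cache:
            hs, _ = forward_hidden(graph, self._embed_params, self.config)
            self._hidden_cache[key] = hs
        return self._hidden_cache[key]

    def _stacked(self, graphs):
        """Hidden states of a batch stacked per step, with molecule owners.

        Because the embedding is frozen, no gradient ever flows into the
        hidden states, so the whole batch can be processed with a few
        dense matmuls instead of per-molecule loops.
        """
        key = tuple(id(g) for g in graphs)
        hit = self._stack_cache.get(key)
        if hit is not None:
            return hit
        hs_all = [self.hidden(g) for g in graphs]
        stacked = [
            np.concatenate([hs[t] for hs in hs_all], axis=0)
            for t in range(self.config.steps + 1)
        ]
        owner = np.concatenate(
            [np.full(g.n_atoms, i, dtype=np.intp) for i, g in enumerate(graphs)]
        )
        # atoms of molecule i occupy the contiguous block starts[i]:starts[i+1]
        starts = np.cumsum([0] + [g.n_atoms for g in graphs[:-1]])
        if len(self._stack_cache) > 64:
            self._stack_cache.clear()
        self._stack_cache[key] = (stacked, owner, starts)
        return self._stack_cache[key]

    def _forward_batch(self, vec, graphs, masks):
        params = self.packer.unpack(vec)
        stacked, owner, starts = self._stacked(graphs)
        B = len(graphs)
        L = self.config.fingerprint
        fp = np.zeros((B, L))
        smx = []
        for t, h in enumerate(stacked):
            logits = h @ params[f"W{t}"].T
            logits -= logits.max(axis=1, keepdims=True)
            s = np.exp(logits)
            s /= s.sum(axis=1, keepdims=True)
            smx.append(s)
            fp += np.add.reduceat(s, starts, axis=0)
        fp_mask = masks.get("fp") if masks else None
        fp_used = fp * fp_mask[None, :] if fp_mask is not None else fp
        a1 = fp_used @ params["U1"].T + params["b1"]
        g1 = np.maximum(a1, 0.0)
        m1 = masks.get("g1") if masks else None
        g1u = g1 * m1[None, :] if m1 is not None else g1
        a2 = g1u @ params["U2"].T + params["b2"]
        g2 = np.maximum(a2, 0.0)
        m2 = masks.get("g2") if masks else None
        g2u = g2 * m2[None, :] if m2 is not None else g2
        out = g2u @ params["U3"].T + params["b3"]
        cache = (params, stacked, owner, smx, fp_used, fp_mask,
                 a1, g1u, m1, a2, g2u, m2)
        return out[:, 0], out[:, 1], cache

    def loss_and_grad(self, vec, graphs, y, masks=None, fixed_variance=None):
        y = np.asarray(y, dtype=float)
        mu, logvar, cache = self._forward_batch(vec, graphs, masks)
        r = y - mu
        if fixed_variance is not None:
            total = float(np.sum(0.5 * (r * r / fixed_variance + np.log(fixed_variance))))
            dmu = -r / fixed_variance
            dlogvar = np.zeros_like(r)
        else:
            inv = np.exp(-logvar)
            if not np.all(np.isfinite(inv)):
                raise FloatingPointError("non-finite aleatoric variance")
            total = float(np.sum(0.5 * (r * r * inv + logvar)))
            dmu = -r * inv
            dlogvar = 0.5 * (1.0 - r * r * inv)
        if not np.isfinite(total):
            raise FloatingPointError("non-finite loss")

        (params, stacked, owner, smx, fp_used, fp_mask,
         a1, g1u, m1, a2, g2u, m2) = cache
        gvec = self.packer.zeros()
        grads = self.packer.unpack(gvec)
        dout = np.stack([dmu, dlogvar], axis=1)  # (B, 2)
        grads["U3"] += dout.T @ g2u
        grads["b3"] += dout.sum(axis=0)
        dg2u = dout @ params["U3"]
        dg2 = dg2u * m2[None, :] if m2 is not None else dg2u
        da2 = dg2 * (a2 > 0)
        grads["U2"] += da2.T @ g1u
        grads["b2"] += da2.sum(axis=0)
        dg1u = da2 @ params["U2"]
        dg1 = dg1u * m1[None, :] if m1 is not None else dg1u
        da1 = dg1 * (a1 > 0)
        grads["U1"] += da1.T @ fp_used
        grads["b1"] += da1.sum(axis=0)
        dfp = da1 @ params["U1"]
        if fp_mask is not None:
            dfp = dfp * fp_mask[None, :]
        dfp_atom = dfp[owner]  # (N_atoms, L)
        for t, h in enumerate(stacked):
            s = smx[t]
            dot = np.einsum("ij,ij->i", s, dfp_atom)
            dpre = s * (dfp_atom - dot[:, None])
            grads[f"W{t}"] += dpre.T @ h
        return total, gvec

    def predict(self, vec, graphs, masks=None):
        mu, logvar, _ = self._forward_batch(vec, graphs, masks)
        return mu, np.exp(logvar)
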