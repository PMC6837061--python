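"""Graph-convolutional fingerprint network with analytic gradients.

The network follows the neural-graph-fingerprint construction. Each atom v
starts from its raw feature vector, h_v^0 = x_v. At step t the message

    m_v^t = sum_{w in N(v)} concat(h_w^{t-1}, e_vw)

is combined with the previous state and passed through a per-degree learned
transition matrix,

    h_v^t = sigmoid(H_{deg(v)}^t @ concat(h_v^{t-1}, m_v^t)),

so hidden-state entries lie in (0, 1) and h_v^t summarises the atomic
environment within graph radius t. The molecule fingerprint is the sum of
per-step softmax readouts,

    f = sum_{t=0..T} sum_v softmax(W_t @ h_v^t),

which is invariant to atom relabelling, and a two-hidden-layer ReLU head
maps f to two outputs: the predicted property mean and the log of the
input-dependent (aleatoric) noise variance.

Everything is plain float64 numpy. Backward passes are written by hand and
checked against central finite differences in the test suite; parameters
live in a single flat vector (see :class:`FlatPacker`) so that Bayesian
ensembles can treat a whole network as one particle.

h^0 keeps the raw atom-feature width F_a (the step-1 transition matrices and
W_0 are sized for F_a, later steps for the hidden width), which keeps the
sum over t = 0..T well-defined without zero-padding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .molgraph import (
    BOND_FEATURE_DIM,
    DEFAULT_ELEMENTS,
    MAX_DEGREE,
    MolecularGraph,
    atom_feature_dim,
)


class FlatPacker:
    """Maps a dict of named arrays to/from one flat float64 vector.

    Unpacked arrays are views into the flat vector, so in-place writes to a
    view update the vector (and vice versa) without copies.
    """

    def __init__(self, shapes: list[tuple[str, tuple[int, ...]]]):
        self.shapes = list(shapes)
        self.slices: dict[str, slice] = {}
        offset = 0
        for name, shape in self.shapes:
            size = int(np.prod(shape, dtype=np.intp)) if shape else 1
            self.slices[name] = slice(offset, offset + size)
            offset += size
        self.size = offset

    def unpack(self, vec: np.ndarray) -> dict[str, np.ndarray]:
        out = {}
        for name, shape in self.shapes:
            out[name] = vec[self.slices[name]].reshape(shape)
        return out

    def zeros(self) -> np.ndarray:
        return np.zeros(self.size, dtype=np.float64)


@dataclass(frozen=True)
class MPNNConfig:
    """Architecture hyperparameters.

    Defaults are the reference configuration: T = 3 message-passing steps,
    128 hidden units per level, fingerprint length 2 * hidden = 256, and a
    two-layer ReLU head of 128 units each.
    """

    steps: int = 3
    hidden: int = 128
    fingerprint: int = 256
    head_hidden: tuple[int, int] = (128, 128)
    elements: tuple[str, ...] = DEFAULT_ELEMENTS
    bond_dim: int = BOND_FEATURE_DIM

    @property
    def atom_dim(self) -> int:
        return atom_feature_dim(self.elements)

    def state_width(self, t: int) -> int:
        """Width of h_v^t (raw features at t = 0, hidden units after)."""
        return self.atom_dim if t == 0 else self.hidden

    def transition_in_dim(self, t: int) -> int:
        """Input width of H_N^t: concat(h^{t-1}, m^t)."""
        w_prev = self.state_width(t - 1)
        return 2 * w_prev + self.bond_dim

    def param_shapes(self) -> list[tuple[str, tuple[int, ...]]]:
        shapes: list[tuple[str, tuple[int, ...]]] = []
        for t in range(1, self.steps + 1):
            shapes.append(
                (f"H{t}", (MAX_DEGREE + 1, self.hidden, self.transition_in_dim(t)))
            )
        for t in range(self.steps + 1):
            shapes.append((f"W{t}", (self.fingerprint, self.state_width(t))))
        h1, h2 = self.head_hidden
        shapes += [
            ("U1", (h1, self.fingerprint)),
            ("b1", (h1,)),
            ("U2", (h2, h1)),
            ("b2", (h2,)),
            ("U3", (2, h2)),
            ("b3", (2,)),
        ]
        return shapes

    def packer(self) -> FlatPacker:
        return FlatPacker(self.param_shapes())


def init_params(config: MPNNConfig, rng: np.random.Generator) -> np.ndarray:
    """Centered-Gaussian init with scale 1/sqrt(fan-in); biases zero."""
    packer = config.packer()
    vec = packer.zeros()
    params = packer.unpack(vec)
    for name, shape in config.param_shapes():
        if name.startswith("b"):
            continue
        fan_in = shape[-1]
        params[name][...] = rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=shape)
    return vec


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax_rows(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# dropout masks


def sample_masks(
    config: MPNNConfig,
    rng: np.random.Generator,
    p: float,
    scope: str = "all",
) -> dict[str, np.ndarray] | None:
    """Bernoulli unit masks for one stochastic forward pass.

    ``scope="all"`` masks every trained unit layer (hidden states at each
    step, the fingerprint, and both head hidden layers); ``scope="top"``
    masks only the layers above the hidden states (fingerprint + head), as
    used for the semi-supervised model. Masks carry the inverted-dropout
    scale 1/(1-p) so expected activations are preserved. Returns None when
    p == 0 (no masking).
    """
    if p == 0.0:
        return None
    if not (0.0 <= p < 1.0):
        raise ValueError(f"dropout probability must be in [0, 1), got {p}")
    scale = 1.0 / (1.0 - p)

    def draw(size: int) -> np.ndarray:
        return (rng.random(size) >= p) * scale

    masks: dict[str, np.ndarray] = {}
    if scope == "all":
        for t in range(1, config.steps + 1):
            masks[f"h{t}"] = draw(config.hidden)
    elif scope != "top":
        raise ValueError(f"unknown dropout scope: {scope!r}")
    masks["fp"] = draw(config.fingerprint)
    masks["g1"] = draw(config.head_hidden[0])
    masks["g2"] = draw(config.head_hidden[1])
    return masks


# ---------------------------------------------------------------------------
# hidden-state propagation (Eqs of message passing)


def forward_hidden(
    graph: MolecularGraph,
    params: dict[str, np.ndarray],
    config: MPNNConfig,
    masks: dict[str, np.ndarray] | None = None,
):
    """Run message passing; returns hidden states per step and a cache.

    ``hs[t]`` is the (n_atoms, width_t) array of h_v^t. The cache holds the
    intermediates the backward pass needs.
    """
    h = graph.atom_features
    hs = [h]
    step_cache = []
    groups = graph.degree_groups()
    if (np.asarray(list(groups)) > MAX_DEGREE).any():
        raise ValueError("atom degree exceeds supported maximum")
    for t in range(1, config.steps + 1):
        w_prev = h.shape[1]
        m = np.zeros((graph.n_atoms, w_prev + config.bond_dim))
        if graph.edge_src.size:
            payload = np.concatenate(
                [h[graph.edge_src], graph.edge_features], axis=1
            )
            np.add.at(m, graph.edge_dst, payload)
        z = np.concatenate([h, m], axis=1)
        Ht = params[f"H{t}"]
        a = np.empty((graph.n_atoms, config.hidden))
        for d, idx in groups.items():
            a[idx] = z[idx] @ Ht[d].T
        h_raw = _sigmoid(a)
        mask = masks.get(f"h{t}") if masks else None
        h = h_raw * mask if mask is not None else h_raw
        step_cache.append((z, h_raw, mask))
        hs.append(h)
    return hs, step_cache


def message_step(
    graph: MolecularGraph,
    h_prev: np.ndarray,
    t: int,
    params: dict[str, np.ndarray],
    config: MPNNConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """One message-passing update: returns (m^t, h^t).

    m_v^t aggregates concat(h_w^{t-1}, e_vw) over bonded neighbours w;
    h_v^t = sigmoid(H_{deg(v)}^t @ concat(h_v^{t-1}, m_v^t)), so entries lie
    in (0, 1). Degree-0 atoms receive a zero message and go through their
    dedicated transition matrix.
    """
    if not 1 <= t <= config.steps:
        raise ValueError(f"step t must be in 1..{config.steps}, got {t}")
    if h_prev.shape[0] != graph.n_atoms:
        raise ValueError("h_prev must hold one vector per atom")
    w_prev = h_prev.shape[1]
    m = np.zeros((graph.n_atoms, w_prev + config.bond_dim))
    if graph.edge_src.size:
        payload = np.concatenate([h_prev[graph.edge_src], graph.edge_features], axis=1)
        np.add.at(m, graph.edge_dst, payload)
    z = np.concatenate([h_prev, m], axis=1)
    Ht = params[f"H{t}"]
    a = np.empty((graph.n_atoms, config.hidden))
    for d, idx in graph.degree_groups().items():
        if d > MAX_DEGREE:
            raise ValueError(f"atom degree {d} exceeds supported maximum")
        a[idx] = z[idx] @ Ht[d].T
    return m, _sigmoid(a)


def backward_hidden(
    graph: MolecularGraph,
    params: dict[str, np.ndarray],
    config: MPNNConfig,
    step_cache,
    d_hs: list[np.ndarray | None],
    grads: dict[str, np.ndarray],
) -> np.ndarray:
    """Backpropagate gradients injected at each step's hidden states.

    ``d_hs[t]`` (or None) is dLoss/dh^t as consumed downstream. Transition-
    matrix gradients are accumulated into ``grads``; the return value is the
    gradient w.r.t. h^0 (the raw atom features, usually discarded).
    """
    groups = graph.degree_groups()
    dh = np.zeros((graph.n_atoms, config.hidden))
    if d_hs[config.steps] is not None:
        dh = dh + d_hs[config.steps]
    for t in range(config.steps, 0, -1):
        z, h_raw, mask = step_cache[t - 1]
        dh_raw = dh * mask if mask is not None else dh
        da = dh_raw * h_raw * (1.0 - h_raw)
        Ht = params[f"H{t}"]
        gH = grads[f"H{t}"]
        dz = np.empty_like(z)
        for d, idx in groups.items():
            gH[d] += da[idx].T @ z[idx]
            dz[idx] = da[idx] @ Ht[d]
        w_prev = config.state_width(t - 1)
        dh_prev = dz[:, :w_prev].copy()
        if graph.edge_src.size:
            # m_d contained h^{t-1}[s] for every directed edge s -> d
            np.add.at(
                dh_prev, graph.edge_src, dz[graph.edge_dst, w_prev : 2 * w_prev]
            )
        if t - 1 >= 1 and d_hs[t - 1] is not None:
            dh_prev = dh_prev + d_hs[t - 1]
        dh = dh_prev
    return dh


# ---------------------------------------------------------------------------
# readout + output head


def readout(
    hs: list[np.ndarray],
    params: dict[str, np.ndarray],
    config: MPNNConfig,
    masks: dict[str, np.ndarray] | None = None,
):
    """Fingerprint f = sum_t sum_v softmax(W_t h_v^t); permutation invariant."""
    fp = np.zeros(config.fingerprint)
    smx = []
    for t, h in enumerate(hs):
        W = params[f"W{t}"]
        if W.shape[1] != h.shape[1]:
            raise ValueError(
                f"readout W{t} expects width {W.shape[1]}, got {h.shape[1]}"
            )
        s = _softmax_rows(h @ W.T)
        smx.append(s)
        fp += s.sum(axis=0)
    mask = masks.get("fp") if masks else None
    fp_used = fp * mask if mask is not None else fp
    return fp_used, (smx, mask)


def backward_readout(
    hs, params, config, cache, dfp: np.ndarray, grads
) -> list[np.ndarray]:
    smx, mask = cache
    if mask is not None:
        dfp = dfp * mask
    d_hs: list[np.ndarray] = []
    for t, h in enumerate(hs):
        s = smx[t]
        dot = s @ dfp
        dpre = s * (dfp[None, :] - dot[:, None])
        grads[f"W{t}"] += dpre.T @ h
        d_hs.append(dpre @ params[f"W{t}"])
    return d_hs


def head_forward(
    fp: np.ndarray,
    params: dict[str, np.ndarray],
    masks: dict[str, np.ndarray] | None = None,
):
    """Two-hidden-layer ReLU head -> (mean, log aleatoric variance)."""
    a1 = params["U1"] @ fp + params["b1"]
    g1 = np.maximum(a1, 0.0)
    m1 = masks.get("g1") if masks else None
    g1u = g1 * m1 if m1 is not None else g1
    a2 = params["U2"] @ g1u + params["b2"]
    g2 = np.maximum(a2, 0.0)
    m2 = masks.get("g2") if masks else None
    g2u = g2 * m2 if m2 is not None else g2
    out = params["U3"] @ g2u + params["b3"]
    cache = (fp, a1, g1u, m1, a2, g2u, m2)
    return float(out[0]), float(out[1]), cache


def head_backward(cache, params, dmu: float, dlogvar: float, grads) -> np.ndarray:
    fp, a1, g1u, m1, a2, g2u, m2 = cache
    dout = np.array([dmu, dlogvar])
    grads["U3"] += np.outer(dout, g2u)
    grads["b3"] += dout
    dg2u = params["U3"].T @ dout
    dg2 = dg2u * m2 if m2 is not None else dg2u
    da2 = dg2 * (a2 > 0)
    grads["U2"] += np.outer(da2, g1u)
    grads["b2"] += da2
    dg1u = params["U2"].T @ da2
    dg1 = dg1u * m1 if m1 is not None else dg1u
    da1 = dg1 * (a1 > 0)
    grads["U1"] += np.outer(da1, fp)
    grads["b1"] += da1
    return params["U1"].T @ da1


@dataclass
class HiddenStates:
    """Per-atom hidden states h_v^t for t = 0..T (h^0 = raw atom features)."""

    states: list[np.ndarray]

    @property
    def steps(self) -> int:
        return len(self.states) - 1


def forward(
    graph: MolecularGraph,
    vec: np.ndarray,
    config: MPNNConfig,
    masks: dict[str, np.ndarray] | None = None,
) -> tuple[float, float]:
    """Full pass: graph -> (predicted mean, log aleatoric variance).

    Deterministic given (graph, parameters, masks); the aleatoric variance
    exp(log_var) is strictly positive by construction.
    """
    params = config.packer().unpack(vec)
    hs, _ = forward_hidden(graph, params, config, masks)
    fp, _ = readout(hs, params, config, masks)
    mu, logvar, _ = head_forward(fp, params, masks)
    return mu, logvar


class MPNNModel:
    """Fully supervised graph-convolutional regressor (Model protocol).

    Exposes ``init`` / ``loss_and_grad`` / ``predict`` over a flat parameter
    vector so the Bayesian engine can treat the whole network as a particle.
    The loss is the heteroscedastic negative log-likelihood

        sum_i [ (y_i - mu_i)^2 / (2 sigma_i^2) + 0.5 log sigma_i^2 ],

    which reduces to half the sum of squared residuals when the variance is
    fixed at 1 (``fixed_variance``).
    """

    dropout_scope = "all"

    def __init__(self, config: MPNNConfig | None = None):
        self.config = config or MPNNConfig()
        self.packer = self.config.packer()
        self.n_params = self.packer.size

    def init(self, rng: np.random.Generator) -> np.ndarray:
        return init_params(self.config, rng)

    def sample_masks(self, rng, p):
        return sample_masks(self.config, rng, p, scope=self.dropout_scope)

    def _hidden(self, graph, params, masks):
        return forward_hidden(graph, params, self.config, masks)

    def _backward_hidden(self, graph, params, cache, d_hs, grads):
        backward_hidden(graph, params, self.config, cache, d_hs, grads)

    def loss_and_grad(
        self,
        vec: np.ndarray,
        graphs: list[MolecularGraph],
        y: np.ndarray,
        masks=None,
        fixed_variance: float | None = None,
    ) -> tuple[float, np.ndarray]:
        """Summed heteroscedastic NLL over the batch and its gradient."""
        config = self.config
        params = self.packer.unpack(vec)
        gvec = self.packer.zeros()
        grads = self.packer.unpack(gvec)
        total = 0.0
        for g, target in zip(graphs, y):
            hs, hcache = self._hidden(g, params, masks)
            fp, rcache = readout(hs, params, config, masks)
            mu, logvar, head_cache = head_forward(fp, params, masks)
            r = target - mu
            if fixed_variance is not None:
                s2 = fixed_variance
                total += 0.5 * (r * r / s2 + np.log(s2))
                dmu, dlogvar = -r / s2, 0.0
            else:
                inv = np.exp(-logvar)
                if not np.isfinite(inv):
                    raise FloatingPointError("non-finite aleatoric variance")
                total += 0.5 * (r * r * inv + logvar)
                dmu = -r * inv
                dlogvar = 0.5 * (1.0 - r * r * inv)
            dfp = head_backward(head_cache, params, dmu, dlogvar, grads)
            d_hs = backward_readout(hs, params, config, rcache, dfp, grads)
            self._backward_hidden(g, params, hcache, d_hs, grads)
        if not np.isfinite(total):
            raise FloatingPointError("non-finite loss")
        return float(total), gvec

    def predict(
        self, vec: np.ndarray, graphs: list[MolecularGraph], masks=None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-graph (mean, aleatoric variance) for one parameter vector."""
        params = self.packer.unpack(vec)
        mus = np.empty(len(graphs))
        s2 = np.empty(len(graphs))
        for i, g in enumerate(graphs):
            hs, _ = self._hidden(g, params, masks)
            fp, _ = readout(hs, params, self.config, masks)
            mu, logvar, _ = head_forward(fp, params, masks)
            mus[i] = mu
            s2[i] = np.exp(logvar)
        return mus, s2
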