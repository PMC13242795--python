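"""The pluggable network Phi and a test oracle.

Phi maps samples drawn from the time-t parameters (plus the pocket context and
fixed-atom flags) to the predicted data-endpoint parameters: per-atom location
mu_hat and a simplex point alpha_hat for the type.  The reference trainable
network is a small E(3)-aware message-passing point-cloud network: edge
features are interatomic distances (rotation/translation invariant),
coordinate updates move along relative-position vectors (equivariant), and
the type head is simplex-normalised.  Any backbone honouring the same
contract — translation- and permutation-equivariant mu_hat, simplex-valued
alpha_hat — can be swapped in.

No autodiff framework is assumed: gradients are provided by a compact
reverse-mode engine over numpy arrays defined here, verified against finite
differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, gammaln, polygamma

__all__ = [
    "PredictorInput",
    "PredictorOutput",
    "build_knn_graph",
    "EGNNPredictor",
    "OraclePredictor",
    "oracle_predictor",
    "Tensor",
]


# --- minimal reverse-mode autodiff over numpy --------------------------------


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward op."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a backward closure list."""

    __slots__ = ("data", "grad", "parents", "requires_grad")

    def __init__(self, data, parents=(), requires_grad=False):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.parents = parents  # tuple of (Tensor, grad_fn)
        self.requires_grad = requires_grad or any(
            p.requires_grad for p, _ in parents
        )

    # -- graph plumbing --

    def backward(self) -> None:
        order, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p, _ in t.parents:
                visit(p)
            order.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(order):
            for p, fn in t.parents:
                if not p.requires_grad:
                    continue
                g = _unbroadcast(fn(t.grad), p.data.shape)
                p.grad = g if p.grad is None else p.grad + g

    # -- primitives --

    def __add__(self, other):
        o = _as_tensor(other)
        return Tensor(
            self.data + o.data,
            ((self, lambda g: g), (o, lambda g: g)),
        )

    __radd__ = __add__

    def __sub__(self, other):
        o = _as_tensor(other)
        return Tensor(
            self.data - o.data,
            ((self, lambda g: g), (o, lambda g: -g)),
        )

    def __rsub__(self, other):
        return _as_tensor(other) - self

    def __mul__(self, other):
        o = _as_tensor(other)
        return Tensor(
            self.data * o.data,
            ((self, lambda g: g * o.data), (o, lambda g: g * self.data)),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = _as_tensor(other)
        return Tensor(
            self.data / o.data,
            (
                (self, lambda g: g / o.data),
                (o, lambda g: -g * self.data / o.data**2),
            ),
        )

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __neg__(self):
        return Tensor(-self.data, ((self, lambda g: -g),))

    def __matmul__(self, other):
        o = _as_tensor(other)
        return Tensor(
            self.data @ o.data,
            (
                (self, lambda g: g @ o.data.T),
                (o, lambda g: self.data.T @ g),
            ),
        )

    def sum(self, axis=None, keepdims=False):
        data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def grad_fn(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return np.broadcast_to(g, shape).copy()

        return Tensor(data, ((self, grad_fn),))

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def exp(self):
        out = np.exp(self.data)
        return Tensor(out, ((self, lambda g: g * out),))

    def log(self):
        return Tensor(np.log(self.data), ((self, lambda g: g / self.data),))

    def tanh(self):
        out = np.tanh(self.data)
        return Tensor(out, ((self, lambda g: g * (1.0 - out**2)),))

    def sqrt(self):
        out = np.sqrt(self.data)
        return Tensor(out, ((self, lambda g: g * 0.5 / out),))

    def abs(self):
        return Tensor(np.abs(self.data), ((self, lambda g: g * np.sign(self.data)),))

    def gammaln(self):
        return Tensor(gammaln(self.data), ((self, lambda g: g * digamma(self.data)),))

    def digamma(self):
        return Tensor(
            digamma(self.data),
            ((self, lambda g: g * polygamma(1, self.data)),),
        )

    def take(self, idx):
        """Row gather: self[idx]."""
        idx = np.asarray(idx, dtype=int)
        shape = self.data.shape

        def grad_fn(g):
            out = np.zeros(shape)
            np.add.at(out, idx, g)
            return out

        return Tensor(self.data[idx], ((self, grad_fn),))


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis=1) -> Tensor:
    datas = [t.data for t in tensors]
    out = np.concatenate(datas, axis=axis)
    parents, start = [], 0

    def make_fn(a, b):
        def grad_fn(g):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            return g[tuple(sl)]

        return grad_fn

    for t in tensors:
        n = t.data.shape[axis]
        parents.append((t, make_fn(start, start + n)))
        start += n
    return Tensor(out, tuple(parents))


def segment_sum(t: Tensor, idx, n: int) -> Tensor:
    """out[i] = sum of rows of t whose segment index is i."""
    idx = np.asarray(idx, dtype=int)
    out = np.zeros((n,) + t.data.shape[1:])
    np.add.at(out, idx, t.data)
    return Tensor(out, ((t, lambda g: g[idx]),))


def softmax_rows(t: Tensor) -> Tensor:
    shifted = t - t.data.max(axis=1, keepdims=True)  # detached shift
    e = shifted.exp()
    return e / e.sum(axis=1, keepdims=True)


# --- KNN graph ---------------------------------------------------------------


def build_knn_graph(coords: np.ndarray, k: int) -> np.ndarray:
    """Directed edges (i, j): j among i's k nearest neighbours (Euclidean).

    Ties are broken by atom index, lower index first.  k is clamped to
    n_atoms - 1 when it exceeds the number of available neighbours.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 atoms for a graph")
    if k < 1:
        raise ValueError("k must be >= 1")
    k = min(k, n - 1)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    edges = []
    idx = np.arange(n)
    for i in range(n):
        others = idx[idx != i]
        # lexsort: primary key distance, secondary key index
        order = np.lexsort((others, d[i, others]))
        for j in others[order[:k]]:
            edges.append((i, j))
    return np.asarray(edges, dtype=int)


# --- predictor contract ------------------------------------------------------


@dataclass
class PredictorInput:
    """Samples drawn at time t plus context, fed to the network.

    coords: (N, 3) ligand coordinate samples (Å; fixed atoms carry exact
    coordinates); type_probs: (N, K) simplex rows sampled from the type
    parameters (fixed atoms carry one-hots); fixed: (N,) flags; t in [0, 1];
    pocket_coords/pocket_types: optional context point cloud.

    location_scale/frame_origin: at time t the sampled locations of generated
    atoms sit at f(t) times the data scale around the working-frame origin;
    callers pass 1/f(t) (clamped) so the network can restore data scale before
    message passing instead of having to learn the amplification itself.
    noise_scale is the known residual scale (1 - f)/f of the restored
    locations around the data: coordinate updates are premultiplied by it, so
    the network estimates an O(1) correction at every time and automatically
    trusts the input as t -> 1.
    """

    coords: np.ndarray
    type_probs: np.ndarray
    fixed: np.ndarray
    t: float
    pocket_coords: np.ndarray | None = None
    pocket_types: np.ndarray | None = None
    location_scale: float = 1.0
    noise_scale: float = 1.0
    frame_origin: np.ndarray = None
    instance_id: object = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.type_probs = np.asarray(self.type_probs, dtype=float)
        self.fixed = np.asarray(self.fixed, dtype=bool).reshape(-1)
        n = self.coords.shape[0]
        if self.type_probs.shape[0] != n or self.fixed.shape[0] != n:
            raise ValueError("inconsistent input shapes")
        if not (0.0 <= self.t <= 1.0):
            raise ValueError("t must lie in [0, 1]")
        if np.any(self.type_probs < -1e-12) or np.any(
            np.abs(self.type_probs.sum(axis=1) - 1.0) > 1e-6
        ):
            raise ValueError("type_probs rows must lie on the simplex")
        if self.frame_origin is None:
            self.frame_origin = np.zeros(3)
        self.frame_origin = np.asarray(self.frame_origin, dtype=float).reshape(3)
        if self.location_scale <= 0:
            raise ValueError("location_scale must be positive")


@dataclass
class PredictorOutput:
    mu_hat: np.ndarray
    alpha_hat: np.ndarray  # (N, K) simplex rows: predicted type Dirac location


def time_embedding(t: float, dim: int = 8) -> np.ndarray:
    freqs = 2.0 ** np.arange(dim // 2)
    ang = 2.0 * np.pi * t * freqs
    return np.concatenate([np.sin(ang), np.cos(ang)])


class EGNNPredictor:
    """Reference trainable point-cloud network.

    Message passing on the joint ligand+pocket graph with knn_k edges per
    node: edge features are multi-scale radial basis functions of interatomic
    distance, aggregation is attention-weighted, and coordinate updates move
    along relative-position vectors.  Node inputs carry, besides type samples
    and flags, radial encodings of the distances to the first few (ordered,
    hence distinguishable) pocket anchors, which breaks the permutation
    symmetry between otherwise identical atoms early in the trajectory.
    hidden_dim and n_layers are deliberately small: this is a desk-scale
    reference backbone, not a reproduction of a production network.
    """

    TIME_DIM = 8
    N_ANCHOR = 4  # pocket anchors encoded as node features (2 RBFs each)

    def __init__(
        self,
        K: int = 4,
        hidden_dim: int = 64,
        n_layers: int = 4,
        knn_k: int = 8,
        seed: int = 0,
    ):
        self.K = K
        self.hidden_dim = hidden_dim
        self.n_layers = n_layers
        self.knn_k = knn_k
        self.seed = seed
        rng = np.random.default_rng(seed)
        F = hidden_dim
        # type probs + fixed flag + pocket flag + t + anchor/origin encodings
        fin = K + 2 + self.TIME_DIM + 2 * self.N_ANCHOR + 2
        self.params: dict[str, Tensor] = {}

        def W(name, shape, scale=None):
            scale = scale if scale is not None else 1.0 / np.sqrt(shape[0])
            self.params[name] = Tensor(
                rng.normal(0.0, scale, size=shape), requires_grad=True
            )

        def b(name, n):
            self.params[name] = Tensor(np.zeros((1, n)), requires_grad=True)

        W("embed_W", (fin, F)); b("embed_b", F)
        for l in range(n_layers):
            W(f"e1_W{l}", (2 * F + 3, F)); b(f"e1_b{l}", F)
            W(f"e2_W{l}", (F, F)); b(f"e2_b{l}", F)
            W(f"a_W{l}", (F, 1)); b(f"a_b{l}", 1)
            W(f"x_W{l}", (F, 1), scale=5e-2); b(f"x_b{l}", 1)
            # origin-pull gate: bias starts at -2 (gentle pull) and the gate
            # saturates to 0 where the input should be trusted
            W(f"g_W{l}", (F, 1), scale=1e-2)
            self.params[f"g_b{l}"] = Tensor(np.full((1, 1), -2.0), requires_grad=True)
            W(f"h_W{l}", (2 * F, F)); b(f"h_b{l}", F)
        W("v_W", (F, K)); b("v_b", K)

    # -- parameter plumbing --

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict) -> None:
        for k, v in state.items():
            self.params[k] = Tensor(np.asarray(v, dtype=float), requires_grad=True)

    def zero_grad(self) -> None:
        for v in self.params.values():
            v.grad = None

    # -- forward --

    def forward(self, inp: PredictorInput) -> tuple[Tensor, Tensor]:
        """Differentiable forward pass; returns (mu_hat, alpha_hat) Tensors."""
        n = inp.coords.shape[0]
        # restore generated-atom locations to data scale in the working frame
        lig_coords = inp.coords.copy()
        gen = ~inp.fixed
        lig_coords[gen] = (
            inp.frame_origin
            + (inp.coords[gen] - inp.frame_origin) * inp.location_scale
        )
        if inp.pocket_coords is not None and len(inp.pocket_coords) > 0:
            pk = np.asarray(inp.pocket_coords, dtype=float).reshape(-1, 3)
            ptypes = np.asarray(inp.pocket_types, dtype=int).reshape(-1)
            ponehot = np.zeros((pk.shape[0], self.K))
            ponehot[np.arange(pk.shape[0]), ptypes] = 1.0
            all_coords = np.concatenate([lig_coords, pk])
            all_types = np.concatenate([inp.type_probs, ponehot])
            fixed_flag = np.concatenate(
                [inp.fixed.astype(float), np.ones(pk.shape[0])]
            )
            pocket_flag = np.concatenate([np.zeros(n), np.ones(pk.shape[0])])
        else:
            all_coords = lig_coords
            all_types = inp.type_probs
            fixed_flag = inp.fixed.astype(float)
            pocket_flag = np.zeros(n)
        m = all_coords.shape[0]
        temb = np.broadcast_to(time_embedding(inp.t, self.TIME_DIM), (m, self.TIME_DIM))
        # pocket-relative positional encodings: RBFs of distances to the first
        # N_ANCHOR pocket atoms (in their given order) and to the frame origin
        anchor_feat = np.zeros((m, 2 * self.N_ANCHOR + 2))
        anchors = (
            list(np.asarray(inp.pocket_coords)[: self.N_ANCHOR])
            if inp.pocket_coords is not None and len(inp.pocket_coords) > 0
            else []
        )
        for j, pt in enumerate(anchors):
            d2a = np.sum((all_coords - pt) ** 2, axis=1)
            anchor_feat[:, 2 * j] = np.exp(-0.125 * d2a)
            anchor_feat[:, 2 * j + 1] = np.exp(-0.02 * d2a)
        d2o = np.sum((all_coords - inp.frame_origin) ** 2, axis=1)
        anchor_feat[:, -2] = np.exp(-0.125 * d2o)
        anchor_feat[:, -1] = np.exp(-0.02 * d2o)
        feat = np.concatenate(
            [all_types, fixed_flag[:, None], pocket_flag[:, None], temb, anchor_feat],
            axis=1,
        )
        edges = build_knn_graph(all_coords, self.knn_k)
        src, dst = edges[:, 0], edges[:, 1]
        # only generated ligand atoms move; context coordinates are exact
        movable = (1.0 - np.maximum(fixed_flag, pocket_flag))[:, None]

        p = self.params
        h = (Tensor(feat) @ p["embed_W"] + p["embed_b"]).tanh()
        x = Tensor(all_coords)
        for l in range(self.n_layers):
            hi, hj = h.take(src), h.take(dst)
            dvec = x.take(src) - x.take(dst)
            d2 = (dvec * dvec).sum(axis=1, keepdims=True)
            d = (d2 + 1e-8).sqrt()
            # bounded multi-scale radial features (Å scales 1, 2, 4)
            rbf = concat([(d2 * -0.5).exp(), (d2 * -0.125).exp(), (d2 * -0.03125).exp()])
            m1 = (concat([hi, hj, rbf]) @ p[f"e1_W{l}"] + p[f"e1_b{l}"]).tanh()
            msg = (m1 @ p[f"e2_W{l}"] + p[f"e2_b{l}"]).tanh()
            # attention weights over each node's incoming edges
            att = ((m1 @ p[f"a_W{l}"] + p[f"a_b{l}"]).tanh() * 3.0).exp()
            att = att / (segment_sum(att, src, m) + 1e-9).take(src)
            s = msg @ p[f"x_W{l}"] + p[f"x_b{l}"]
            x = x + segment_sum(dvec / (d + 1.0) * s * att, src, m) * (
                movable * inp.noise_scale
            )
            # global pull toward the frame origin: the only update channel
            # that stays informative when all pairwise distances are large
            gate = ((h @ p[f"g_W{l}"] + p[f"g_b{l}"]).tanh() + 1.0) * 0.5
            x = x + (Tensor(np.broadcast_to(inp.frame_origin, (m, 3)).copy()) - x) * (
                gate * movable
            )
            agg = segment_sum(msg * att, src, m)
            h = h + (concat([h, agg]) @ p[f"h_W{l}"] + p[f"h_b{l}"]).tanh()
        # ligand rows only
        lig = np.arange(n)
        mu_hat = x.take(lig)
        alpha_hat = softmax_rows(h.take(lig) @ p["v_W"] + p["v_b"])
        return mu_hat, alpha_hat

    def predict(self, inp: PredictorInput) -> PredictorOutput:
        mu_hat, alpha_hat = self.forward(inp)
        out_mu = mu_hat.data.copy()
        out_a = alpha_hat.data.copy()
        # fixed atoms pass through verbatim: their Diracs are not re-predicted
        out_mu[inp.fixed] = inp.coords[inp.fixed]
        out_a[inp.fixed] = inp.type_probs[inp.fixed]
        return PredictorOutput(mu_hat=out_mu, alpha_hat=out_a)

    def config_dict(self) -> dict:
        return {
            "K": self.K,
            "hidden_dim": self.hidden_dim,
            "n_layers": self.n_layers,
            "knn_k": self.knn_k,
            "seed": self.seed,
        }


class OraclePredictor:
    """Test double: ignores the noisy input and emits the true data parameters.

    Built from a dataset of ground-truth molecules keyed by instance id; a
    sampler driven by this oracle must reproduce each molecule exactly, which
    validates the parameter-update machinery independently of any learning.
    """

    def __init__(self, dataset: dict):
        self.dataset = dict(dataset)

    def predict(self, inp: PredictorInput) -> PredictorOutput:
        if inp.instance_id not in self.dataset:
            raise KeyError(f"unknown instance id {inp.instance_id!r}")
        mol = self.dataset[inp.instance_id]
        if mol.n_atoms != inp.coords.shape[0]:
            raise ValueError("oracle molecule does not match input atom count")
        mu = mol.coords.copy()
        alpha = mol.onehot_types()
        mu[inp.fixed] = inp.coords[inp.fixed]
        alpha[inp.fixed] = inp.type_probs[inp.fixed]
        return PredictorOutput(mu_hat=mu, alpha_hat=alpha)


def oracle_predictor(dataset: dict) -> OraclePredictor:
    """Build an oracle predictor from {instance_id: Molecule}."""
    return OraclePredictor(dataset)
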