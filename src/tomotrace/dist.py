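"""Geometry-invariant edge-probability transformer for point-cloud instance
segmentation.

The network never sees raw coordinates: the input is the dense matrix of
Gaussian edge weights exp(-d_ij^2 / (2 s^2)), expanded over a radial basis.
Node features start from a single learned vector shared by all points, so
the whole computation is invariant to rigid motion and equivariant to point
permutation by construction. Each transformer block attends between nodes
with attention logits biased by the current edge state, then updates each
edge from its two incident node features. A linear head over the final edge
state, symmetrised by averaging the (i,j) and (j,i) logits, yields the
connection-probability matrix.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .core import EdgeMatrix, PointCloud, median_nn_distance, pairwise_edge_weights
from .nn import EarlyStopping, LayerNorm, Linear, Module, NAdam, Parameter, Tensor

__all__ = [
    "DistModelConfig", "TrainConfig", "DistModel", "build_pair_representation",
    "predict_edges", "predict_edges_chunked", "train_dist",
    "save_checkpoint", "load_checkpoint",
]


@dataclass
class DistModelConfig:
    n_layers: int = 6
    node_dim: int = 32
    edge_dim: int = 32
    n_heads: int = 4
    n_rbf: int = 16
    hidden_dim: int = 64
    scale_s: float | None = None     # nm; None = median nn distance per cloud
    max_points: int = 2000           # cap per forward pass (500 for training)
    seed: int = 0

    def __post_init__(self):
        for name in ("n_layers", "node_dim", "edge_dim", "n_heads", "n_rbf", "hidden_dim"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.edge_dim % self.n_heads:
            raise ValueError("edge_dim must be divisible by n_heads")
        if self.node_dim % self.n_heads:
            raise ValueError("node_dim must be divisible by n_heads")


@dataclass
class TrainConfig:
    learning_rate: float = 1e-5
    patience_epochs: int = 100
    ma_window: int = 1
    loss: str = "BCE"
    pos_weight: float = 3.0
    seed: int = 0
    max_epochs: int = 1000

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.patience_epochs < 1:
            raise ValueError("patience_epochs must be >= 1")
        if self.loss != "BCE":
            raise ValueError("only BCE loss is supported")


def build_pair_representation(cloud: PointCloud, config: DistModelConfig):
    """Initial features: RBF expansion of the Gaussian edge weights.

    Returns (node_init, edge_features) as plain arrays; node_init is just a
    placeholder of shape (n, 0) — actual node features come from the model's
    learned start vector so that coordinates never leak in.
    """
    n = cloud.n_points
    if n > config.max_points:
        raise ValueError(
            f"cloud has {n} points > max_points={config.max_points}; "
            "use predict_edges_chunked")
    if n == 0:
        return np.empty((0, 0)), np.empty((0, 0, config.n_rbf))
    w = pairwise_edge_weights(cloud, config.scale_s).values
    centers = np.linspace(0.0, 1.0, config.n_rbf)
    sigma = 1.0 / (config.n_rbf - 1)
    feats = np.exp(-((w[..., None] - centers) ** 2) / (2.0 * sigma ** 2))
    return np.empty((n, 0)), feats


class _Block(Module):
    """One pre-norm transformer block with edge-biased attention and an
    edge update from incident node pairs."""

    def __init__(self, cfg: DistModelConfig, rng):
        d, de, h = cfg.node_dim, cfg.edge_dim, cfg.hidden_dim
        self.ln_attn = LayerNorm(d)
        self.ln_bias = LayerNorm(de)
        self.q = Linear(d, d, rng)
        self.k = Linear(d, d, rng)
        self.v = Linear(d, d, rng)
        self.attn_bias = Linear(de, cfg.n_heads, rng)
        self.attn_out = Linear(d, d, rng)
        self.ln_mlp = LayerNorm(d)
        self.mlp1 = Linear(d, 2 * d, rng)
        self.mlp2 = Linear(2 * d, d, rng)
        self.ln_edge = LayerNorm(de)
        self.ln_node_e = LayerNorm(d)
        self.edge_from_i = Linear(d, h, rng, bias=False)
        self.edge_from_j = Linear(d, h, rng, bias=False)
        self.edge_from_e = Linear(de, h, rng)
        self.edge_out = Linear(h, de, rng)
        self.n_heads = cfg.n_heads
        self.head_dim = d // cfg.n_heads

    def __call__(self, H: Tensor, E: Tensor):
        n = H.shape[0]
        nh, dh = self.n_heads, self.head_dim
        Hn = self.ln_attn(H)
        q = self.q(Hn).reshape(n, nh, dh).transpose(1, 0, 2)
        k = self.k(Hn).reshape(n, nh, dh).transpose(1, 0, 2)
        v = self.v(Hn).reshape(n, nh, dh).transpose(1, 0, 2)
        bias = self.attn_bias(self.ln_bias(E)).transpose(2, 0, 1)   # (heads, n, n)
        logits = (q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(dh)) + bias
        attn = logits.softmax(axis=-1)
        out = (attn @ v).transpose(1, 0, 2).reshape(n, nh * dh)
        H = H + self.attn_out(out)
        H = H + self.mlp2(self.mlp1(self.ln_mlp(H)).leaky_relu())

        Hn2 = self.ln_node_e(H)
        xi = self.edge_from_i(Hn2).reshape(n, 1, -1)
        xj = self.edge_from_j(Hn2).reshape(1, n, -1)
        xe = self.edge_from_e(self.ln_edge(E))
        E = E + self.edge_out((xi + xj + xe).leaky_relu())
        return H, E


class DistModel(Module):
    """Edge-probability transformer over point clouds."""

    def __init__(self, config: DistModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.node_start = Parameter(rng.normal(0.0, 0.1, size=(1, config.node_dim)))
        self.edge_in = Linear(config.n_rbf, config.edge_dim, rng)
        self.blocks = [_Block(config, rng) for _ in range(config.n_layers)]
        self.ln_head = LayerNorm(config.edge_dim)
        self.head = Linear(config.edge_dim, 1, rng)

    def forward_logits(self, cloud: PointCloud) -> Tensor:
        """Symmetrised connection logits, shape (n, n)."""
        n = cloud.n_points
        _, feats = build_pair_representation(cloud, self.config)
        E = self.edge_in(Tensor(feats))
        H = self.node_start + Tensor(np.zeros((n, self.config.node_dim)))
        for block in self.blocks:
            H, E = block(H, E)
        logits = self.head(self.ln_head(E)).reshape(n, n)
        return (logits + logits.transpose(1, 0)) * 0.5

    def __call__(self, cloud: PointCloud) -> Tensor:
        return self.forward_logits(cloud)


def predict_edges(model: DistModel, cloud: PointCloud) -> EdgeMatrix:
    """Predicted connection probabilities: symmetric, entries in (0, 1),
    zero diagonal."""
    n = cloud.n_points
    if n == 0:
        return EdgeMatrix(np.zeros((0, 0)), kind="probability")
    if cloud.n_dims not in (2, 3):
        raise ValueError("cloud must be 2D or 3D")
    logits = model.forward_logits(cloud)
    probs = 1.0 / (1.0 + np.exp(-logits.data))
    np.fill_diagonal(probs, 0.0)
    return EdgeMatrix(probs, kind="probability")


def predict_edges_chunked(model: DistModel, cloud: PointCloud) -> EdgeMatrix:
    """Prediction for clouds beyond ``max_points``: overlapping spatial
    chunks (50% overlap along the longest axis) predicted independently,
    overlapping pair probabilities merged by maximum. Pairs that never share
    a chunk get probability 0."""
    n = cloud.n_points
    cap = model.config.max_points
    if n <= cap:
        return predict_edges(model, cloud)
    axis = int(np.argmax(np.ptp(cloud.coords, axis=0)))
    x = cloud.coords[:, axis]
    lo, hi = float(x.min()), float(x.max())
    # shrink the window until every window holds at most ``cap`` points;
    # spatial windows (not index windows) keep well-separated structures in
    # disjoint chunks
    window = hi - lo
    for _ in range(60):
        starts = np.arange(lo, hi + 1e-9, window / 2.0)
        chunks = [np.flatnonzero((x >= s) & (x <= s + window)) for s in starts]
        chunks = [c for c in chunks if len(c) > 0]
        if max(len(c) for c in chunks) <= cap:
            break
        window *= 0.8
    else:
        # degenerate geometry (many coincident points): fall back to index slices
        order = np.argsort(x, kind="stable")
        chunks = [order[s:s + cap] for s in range(0, n, cap // 2)]
    probs = np.zeros((n, n))
    for idx in chunks:
        sub = predict_edges(model, cloud.subset(idx))
        probs[np.ix_(idx, idx)] = np.maximum(probs[np.ix_(idx, idx)], sub.values)
    np.fill_diagonal(probs, 0.0)
    return EdgeMatrix(probs, kind="probability")


def _bce_loss(logits: Tensor, target: np.ndarray, pos_weight: float = 1.0) -> Tensor:
    """Weighted mean per-pair binary cross-entropy over off-diagonal
    entries, computed from logits for numerical stability.

    ``pos_weight`` up-weights the rare positive (connected) pairs: a chain
    of n points has only ~n positive entries among n^2 pairs.
    """
    n = target.shape[0]
    mask = (1.0 - np.eye(n)) * np.where(target > 0, pos_weight, 1.0)
    per_pair = logits.softplus() - logits * Tensor(target)
    return (per_pair * Tensor(mask)).sum() * (1.0 / max(mask.sum(), 1.0))


def validation_loss(model: DistModel, val_set) -> float:
    losses = []
    for cloud, gt in val_set:
        logits = model.forward_logits(cloud)
        losses.append(float(_bce_loss(logits, gt.values).data))
    return float(np.mean(losses))


def train_dist(train_set, val_set, model_config: DistModelConfig,
               train_config: TrainConfig, val_evaluator=None):
    """Train the edge transformer with NAdam on per-pair BCE.

    ``train_set``/``val_set`` are sequences of (PointCloud, binary
    EdgeMatrix) pairs; one cloud per optimisation step. Training stops at
    ``max_epochs`` or when the moving average of validation loss has not
    improved for ``patience_epochs`` consecutive epochs. Seeded runs are
    reproducible. ``val_evaluator`` (model -> loss) overrides the default
    validation pass; returns (model, history) with per-epoch train/val
    losses.
    """
    if len(train_set) == 0:
        raise ValueError("training set is empty")
    model = DistModel(model_config)
    opt = NAdam(model.parameters(), lr=train_config.learning_rate)
    stopper = EarlyStopping(train_config.patience_epochs, train_config.ma_window)
    rng = np.random.default_rng(train_config.seed)
    history = {"epoch": [], "train_loss": [], "val_loss": []}
    for epoch in range(1, train_config.max_epochs + 1):
        order = rng.permutation(len(train_set))
        epoch_losses = []
        for i in order:
            cloud, gt = train_set[i]
            if cloud.n_points < 2:
                continue
            logits = model.forward_logits(cloud)
            loss = _bce_loss(logits, gt.values, train_config.pos_weight)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        if val_evaluator is not None:
            val_loss = float(val_evaluator(model))
        elif len(val_set):
            val_loss = validation_loss(model, val_set)
        else:
            val_loss = float(np.mean(epoch_losses))
        history["epoch"].append(epoch)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["val_loss"].append(val_loss)
        if stopper.update(val_loss):
            break
    return model, history


def save_checkpoint(model: DistModel, path):
    state = model.state_dict()
    np.savez(path, __config__=json.dumps(asdict(model.config)),
             **{k: v for k, v in state.items()})


def load_checkpoint(path) -> DistModel:
    archive = np.load(path, allow_pickle=False)
    config = DistModelConfig(**json.loads(str(archive["__config__"])))
    model = DistModel(config)
    model.load_state_dict({k: archive[k] for k in archive.files if k != "__config__"})
    return model
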