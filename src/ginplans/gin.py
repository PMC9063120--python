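"""Graph Isomorphism Network fingerprints (GINFP).

The encoder stacks K graph-convolution layers.  At layer k each node v
aggregates

    a_v = (1 - eps_k) * h_v + sum_{u in N(v)} h_u

(neighbour embeddings are *summed*, never averaged — sum aggregation is
what lets the network separate nodes by neighbour multiset), then maps
a_v through that layer's node MLP.  ``eps_k`` is a trainable scalar per
layer.  The ``(1 - eps)`` form is kept as the default; ``epsilon_sign``
switches to the ``(1 + eps)`` convention of the original GIN
formulation (the aggregate coefficient is ``1 + epsilon_sign * eps``,
default sign -1).

The graph-level embedding — the GINFP — sums each node's embeddings
across all K layers and then mean-pools over nodes, giving a fixed
``embed_dim`` vector (300 by default).  Pretraining attaches a two-layer
MLP head that reconstructs the molecule's binary ECFP through a sigmoid,
trained with mean per-bit binary cross-entropy; the head is discarded at
embedding time.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import sparse

from . import nn
from .chem import MolecularGraph, NODE_FEATURE_DIM, graphs_from_smiles

logger = logging.getLogger(__name__)


@dataclass
class GINConfig:
    n_layers: int = 5
    node_mlp_hidden: tuple[int, ...] = (1024, 512)
    embed_dim: int = 300
    head_hidden: tuple[int, ...] = (512,)
    out_dim: int = 2048
    epsilon_sign: int = -1
    seed: int = 0

    def __post_init__(self):
        if self.embed_dim < 1:
            raise ValueError("embed_dim must be >= 1")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.epsilon_sign not in (-1, 1):
            raise ValueError("epsilon_sign must be +1 or -1")


@dataclass
class GINParams:
    """Trainable state: input projection, per-layer node MLPs and epsilons,
    and the ECFP-reconstruction head."""

    projection: nn.MLPNet
    layer_mlps: list[nn.MLPNet]
    epsilons: list[np.ndarray]          # scalar arrays, one per layer
    epsilon_grads: list[np.ndarray]
    head: nn.MLPNet
    node_feature_dim: int = NODE_FEATURE_DIM

    def parameters(self):
        out = list(self.projection.parameters())
        for mlp in self.layer_mlps:
            out.extend(mlp.parameters())
        out.extend(zip(self.epsilons, self.epsilon_grads))
        out.extend(self.head.parameters())
        return out


def init_params(config: GINConfig, node_feature_dim: int = NODE_FEATURE_DIM,
                seed: int | None = None) -> GINParams:
    rng = np.random.default_rng(config.seed if seed is None else seed)
    projection = nn.MLPNet([node_feature_dim, config.embed_dim], rng)
    layer_dims = [config.embed_dim, *config.node_mlp_hidden, config.embed_dim]
    layer_mlps = [nn.MLPNet(layer_dims, rng) for _ in range(config.n_layers)]
    epsilons = [np.zeros((), dtype=nn.DTYPE) for _ in range(config.n_layers)]
    epsilon_grads = [np.zeros((), dtype=nn.DTYPE) for _ in range(config.n_layers)]
    head = nn.MLPNet([config.embed_dim, *config.head_hidden, config.out_dim], rng)
    return GINParams(projection, layer_mlps, epsilons, epsilon_grads, head,
                     node_feature_dim)


# ---------------------------------------------------------------------------
# Forward / backward over a packed batch of graphs


def _pack(graphs: list[MolecularGraph]):
    """Concatenate graphs into one node matrix, block adjacency, and a
    graph-id vector for pooling."""
    X = np.vstack([g.node_features for g in graphs]).astype(nn.DTYPE)
    seg = np.concatenate(
        [np.full(g.n_nodes, i, dtype=np.int64) for i, g in enumerate(graphs)]
    )
    rows, cols, offset = [], [], 0
    for g in graphs:
        if g.n_edges:
            i, j = g.edges[:, 0] + offset, g.edges[:, 1] + offset
            rows.append(np.concatenate([i, j]))
            cols.append(np.concatenate([j, i]))
        offset += g.n_nodes
    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
        A = sparse.csr_matrix(
            (np.ones(r.size, dtype=nn.DTYPE), (r, c)), shape=(offset, offset)
        )
    else:
        A = sparse.csr_matrix((offset, offset), dtype=nn.DTYPE)
    counts = np.bincount(seg, minlength=len(graphs)).astype(nn.DTYPE)
    return X, A, seg, counts


def _forward(params: GINParams, config: GINConfig, X, A, seg, counts):
    """Returns (graph embeddings, cache) for a packed batch."""
    h = params.projection.forward(X)
    h_sum = np.zeros_like(h)
    h_inputs = []  # h entering each layer (the h^{(k-1)} of the update rule)
    for k in range(config.n_layers):
        h_inputs.append(h)
        coef = nn.DTYPE(1.0) + nn.DTYPE(config.epsilon_sign) * params.epsilons[k]
        agg = coef * h + A @ h
        h = params.layer_mlps[k].forward(agg)
        h_sum = h_sum + h
    n_graphs = counts.size
    pooled = np.zeros((n_graphs, h_sum.shape[1]), dtype=nn.DTYPE)
    np.add.at(pooled, seg, h_sum)
    embeddings = pooled / counts[:, None]
    cache = {"h_inputs": h_inputs, "A": A, "seg": seg, "counts": counts}
    return embeddings, cache


def _backward(params: GINParams, config: GINConfig, d_embeddings, cache):
    """Backpropagate from graph embeddings into all GIN parameters."""
    seg, counts, A = cache["seg"], cache["counts"], cache["A"]
    d_hsum = (d_embeddings / counts[:, None])[seg]
    d_carry = np.zeros_like(d_hsum)
    for k in range(config.n_layers - 1, -1, -1):
        d_hk = d_hsum + d_carry
        d_agg = params.layer_mlps[k].backward(d_hk)
        h_in = cache["h_inputs"][k]
        params.epsilon_grads[k] += nn.DTYPE(config.epsilon_sign) * np.sum(d_agg * h_in)
        coef = nn.DTYPE(1.0) + nn.DTYPE(config.epsilon_sign) * params.epsilons[k]
        d_carry = coef * d_agg + A @ d_agg  # A symmetric
    # the projection output feeds only layer 1 (it is not part of the
    # cross-layer sum), so the gradient reaching it is the final carry
    params.projection.backward(d_carry)


def gin_node_update(k: int, graph: MolecularGraph, h_prev: np.ndarray,
                    params: GINParams, config: GINConfig) -> np.ndarray:
    """One layer's node update on a single graph (functional form).

    ``a_v = (1 + epsilon_sign * eps_k) h_v + sum_{u in N(v)} h_u`` followed
    by layer k's node MLP.  An isolated node contributes an empty neighbour
    sum, so with eps=0 its aggregate is its own embedding.
    """
    h_prev = np.asarray(h_prev, dtype=nn.DTYPE)
    if h_prev.ndim != 2 or h_prev.shape[0] != graph.n_nodes:
        raise ValueError(
            f"h_prev must have one row per node: got {h_prev.shape} "
            f"for {graph.n_nodes} nodes"
        )
    coef = nn.DTYPE(1.0) + nn.DTYPE(config.epsilon_sign) * params.epsilons[k]
    agg = coef * h_prev + graph.adjacency() @ h_prev
    return params.layer_mlps[k].forward(agg)


def gin_aggregate(k: int, graph: MolecularGraph, h_prev: np.ndarray,
                  params: GINParams, config: GINConfig) -> np.ndarray:
    """The pre-MLP aggregate a_v of layer k (exposed for inspection)."""
    h_prev = np.asarray(h_prev, dtype=nn.DTYPE)
    if h_prev.ndim != 2 or h_prev.shape[0] != graph.n_nodes:
        raise ValueError("h_prev must have one row per node")
    coef = nn.DTYPE(1.0) + nn.DTYPE(config.epsilon_sign) * params.epsilons[k]
    return coef * h_prev + graph.adjacency() @ h_prev


def graph_embed(graph: MolecularGraph, params: GINParams,
                config: GINConfig) -> np.ndarray:
    """GINFP of a single graph: per-node embeddings summed over all layers,
    then mean-pooled over nodes.  Length ``config.embed_dim``."""
    if graph.n_nodes == 0:
        raise ValueError("cannot embed an empty graph (mean over zero nodes)")
    X, A, seg, counts = _pack([graph])
    emb, _ = _forward(params, config, X, A, seg, counts)
    return emb[0]


# ---------------------------------------------------------------------------
# Pretraining (ECFP reconstruction)


def pretrain(dataset: list[tuple[MolecularGraph, np.ndarray]],
             config: GINConfig, epochs: int = 100,
             validation_fraction: float = 0.1, seed: int = 0,
             lr: float = 1e-3, batch_size: int = 64, patience: int = 5):
    """Train the GIN to reconstruct ECFP bits from molecular graphs.

    Minimises mean per-bit BCE between sigmoid(head(GINFP)) and the binary
    fingerprint.  Early-stops when validation loss has not improved for
    ``patience`` epochs and restores the best parameters.  Returns
    ``(params, history)`` with per-epoch train/validation losses.
    """
    if not dataset:
        raise ValueError("pretraining dataset is empty")
    for g, fp in dataset:
        if fp.shape[0] != config.out_dim:
            raise ValueError(
                f"fingerprint length {fp.shape[0]} != config.out_dim {config.out_dim}"
            )
    rng = np.random.default_rng(seed)
    params = init_params(config, dataset[0][0].node_features.shape[1], seed=seed)
    adam = nn.Adam(params.parameters(), lr=lr)

    idx = rng.permutation(len(dataset))
    n_val = max(1, int(round(validation_fraction * len(dataset)))) if len(dataset) > 1 else 0
    val_idx, train_idx = idx[:n_val], idx[n_val:]
    if train_idx.size == 0:
        train_idx = val_idx
    val_batch = [dataset[i] for i in val_idx]
    history = {"train_loss": [], "val_loss": []}
    best_loss, best_state, since_best = np.inf, None, 0

    def eval_loss(batch):
        if not batch:
            return float("nan")
        X, A, seg, counts = _pack([g for g, _ in batch])
        Y = np.vstack([fp for _, fp in batch]).astype(nn.DTYPE)
        emb, _ = _forward(params, config, X, A, seg, counts)
        logits = params.head.forward(emb)
        loss, _ = nn.sigmoid_bce(logits, Y)
        return loss

    for _epoch in range(epochs):
        order = rng.permutation(train_idx)
        total, seen = 0.0, 0
        for start in range(0, order.size, batch_size):
            batch = [dataset[i] for i in order[start:start + batch_size]]
            X, A, seg, counts = _pack([g for g, _ in batch])
            Y = np.vstack([fp for _, fp in batch]).astype(nn.DTYPE)
            emb, cache = _forward(params, config, X, A, seg, counts)
            logits = params.head.forward(emb)
            loss, dlogits = nn.sigmoid_bce(logits, Y)
            d_emb = params.head.backward(dlogits)
            _backward(params, config, d_emb, cache)
            adam.step()
            total += loss * len(batch)
            seen += len(batch)
        train_loss = total / max(seen, 1)
        val_loss = eval_loss(val_batch) if val_batch else train_loss
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        if val_loss < best_loss - 1e-6:
            best_loss = val_loss
            best_state = nn.snapshot(params.parameters())
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                logger.info("pretraining early stop at epoch %d", _epoch + 1)
                break
    if best_state is not None:
        nn.restore(params.parameters(), best_state)
    return params, history


def reconstruct_ecfp_probs(graphs: list[MolecularGraph], params: GINParams,
                           config: GINConfig) -> np.ndarray:
    """Per-bit reconstruction probabilities sigmoid(head(GINFP))."""
    X, A, seg, counts = _pack(graphs)
    emb, _ = _forward(params, config, X, A, seg, counts)
    return nn.sigmoid(params.head.forward(emb).astype(np.float64))


def embed_graphs(graphs: list[MolecularGraph], params: GINParams,
                 config: GINConfig, batch_size: int = 256) -> np.ndarray:
    rows = []
    for start in range(0, len(graphs), batch_size):
        chunk = graphs[start:start + batch_size]
        X, A, seg, counts = _pack(chunk)
        emb, _ = _forward(params, config, X, A, seg, counts)
        rows.append(emb)
    return np.vstack(rows) if rows else np.zeros((0, config.embed_dim), dtype=nn.DTYPE)


def embed_dataset(smiles_list: list[str], params: GINParams,
                  config: GINConfig) -> tuple[np.ndarray, list[int]]:
    """GINFP matrix, one row per loadable SMILES in input order.

    Unloadable SMILES are dropped; their indices are logged and returned.
    """
    graphs, dropped = graphs_from_smiles(smiles_list)
    return embed_graphs(graphs, params, config), dropped


# ---------------------------------------------------------------------------
# Checkpoints


def save_checkpoint(path, params: GINParams, config: GINConfig) -> None:
    """Single-file checkpoint (.npz) with the config embedded as JSON."""
    arrays = {f"param_{i}": p for i, (p, _) in enumerate(params.parameters())}
    arrays["config_json"] = np.array(json.dumps(asdict(config)))
    arrays["node_feature_dim"] = np.array(params.node_feature_dim)
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[GINParams, GINConfig]:
    data = np.load(path, allow_pickle=False)
    cfg_dict = json.loads(str(data["config_json"]))
    cfg_dict["node_mlp_hidden"] = tuple(cfg_dict["node_mlp_hidden"])
    cfg_dict["head_hidden"] = tuple(cfg_dict["head_hidden"])
    config = GINConfig(**cfg_dict)
    params = init_params(config, int(data["node_feature_dim"]))
    for i, (p, _) in enumerate(params.parameters()):
        p[...] = data[f"param_{i}"]
    return params, config
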