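"""Geometric vector perceptron encoder for local-structure graphs.

The encoder operates jointly on scalar (rotation-invariant) and vector
(rotation-equivariant) channels: scalars only ever see vector norms, vectors
are only linearly mixed and gated by scalars, so scalar outputs are invariant
and vector outputs equivariant under any rigid motion of the input
coordinates. Per-residue structure embeddings are the mean over the local
graph's per-node scalar outputs.

Pretraining is a coordinate-denoising task: C-alpha positions are perturbed
with isotropic 3D Gaussian noise (the N and C atoms following rigidly) and
the encoder's vector head is trained to predict each node's displacement.
"""

from __future__ import annotations

import numpy as np

from .core import ProteinStructure
from .graphs import (
    DEFAULT_NEIGHBORS,
    EDGE_SCALAR_DIM,
    EDGE_VECTOR_DIM,
    NODE_SCALAR_DIM,
    NODE_VECTOR_DIM,
    LocalStructureGraph,
    ProteinGraphBatch,
    build_protein_graphs,
)
from .nn import AdamW, LayerNorm, Linear, Module, Tensor, concatenate, no_grad

__all__ = ["GVP", "GeometricEncoder", "pretrain_encoder_denoising"]


class GVP(Module):
    """One geometric vector perceptron layer (vector-gating variant)."""

    def __init__(
        self,
        in_s: int,
        in_v: int,
        out_s: int,
        out_v: int,
        rng: np.random.Generator,
        activate: bool = True,
    ):
        super().__init__()
        self.out_v = out_v
        self.activate = activate
        h = max(in_v, out_v, 1)
        self.Wh = Tensor(rng.normal(0, 1.0 / np.sqrt(in_v), size=(in_v, h)), requires_grad=True)
        self.Ws = Linear(in_s + h, out_s, rng)
        if out_v:
            self.Wu = Tensor(rng.normal(0, 1.0 / np.sqrt(h), size=(h, out_v)), requires_grad=True)
            self.Wg = Linear(out_s, out_v, rng)

    def __call__(self, s: Tensor, V: Tensor) -> tuple[Tensor, Tensor | None]:
        Vh = (V.swapaxes(-1, -2) @ self.Wh).swapaxes(-1, -2)  # (n, h, 3)
        norms = Vh.norm(axis=-1)
        s_out = self.Ws(concatenate([s, norms], axis=-1))
        if self.activate:
            s_out = s_out.relu()
        if not self.out_v:
            return s_out, None
        Vu = (Vh.swapaxes(-1, -2) @ self.Wu).swapaxes(-1, -2)  # (n, out_v, 3)
        gate = self.Wg(s_out).sigmoid()
        V_out = Vu * gate.reshape(gate.shape[0], self.out_v, 1)
        return s_out, V_out


class _MessageLayer(Module):
    """Edge-message GVP layer with mean aggregation and residual update."""

    def __init__(self, ns: int, nv: int, rng: np.random.Generator):
        super().__init__()
        self.msg = GVP(2 * ns + EDGE_SCALAR_DIM, 2 * nv + EDGE_VECTOR_DIM, ns, nv, rng)
        self.ff = GVP(ns, nv, ns, nv, rng)
        self.norm1 = LayerNorm(ns)
        self.norm2 = LayerNorm(ns)

    def __call__(self, s, V, batch: ProteinGraphBatch, agg: Tensor):
        src, dst = batch.edge_src, batch.edge_dst
        es = Tensor(batch.edge_scalars)
        ev = Tensor(batch.edge_vectors)
        ms_in = concatenate([s.take(src), s.take(dst), es], axis=-1)
        mv_in = concatenate([V.take(src), V.take(dst), ev], axis=1)
        ms, mv = self.msg(ms_in, mv_in)
        n_nodes, nv = V.shape[0], V.shape[1]
        agg_s = agg @ ms
        agg_v = (agg @ mv.reshape(mv.shape[0], -1)).reshape(n_nodes, nv, 3)
        s = self.norm1(s + agg_s)
        V = V + agg_v
        fs, fv = self.ff(s, V)
        return self.norm2(s + fs), V + fv


class GeometricEncoder(Module):
    """Stacked GVP message-passing encoder producing per-node embeddings.

    Parameters
    ----------
    d : int
        Output embedding dimension of a local structure.
    ns, nv : int
        Hidden scalar / vector channel widths.
    n_layers : int
        Message-passing layers.
    seed : int
        Initialization seed.
    """

    def __init__(self, d: int = 32, ns: int = 32, nv: int = 8, n_layers: int = 2, seed: int = 0):
        super().__init__()
        self.d = d
        self.ns = ns
        self.nv = nv
        self.n_layers = n_layers
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.embed = GVP(NODE_SCALAR_DIM, NODE_VECTOR_DIM, ns, nv, rng)
        self.layers = [_MessageLayer(ns, nv, rng) for _ in range(n_layers)]
        self.out_proj = Linear(ns, d, rng)
        # vector head used only by denoising pretraining
        self.denoise_head = GVP(ns, nv, ns, 1, rng, activate=False)

    # -- forward passes -------------------------------------------------------
    def _aggregation_matrix(self, batch: ProteinGraphBatch) -> Tensor:
        n_nodes = batch.node_scalars.shape[0]
        n_edges = len(batch.edge_dst)
        indeg = np.bincount(batch.edge_dst, minlength=n_nodes).astype(np.float64)
        indeg[indeg == 0] = 1.0
        A = np.zeros((n_nodes, n_edges))
        A[batch.edge_dst, np.arange(n_edges)] = 1.0 / indeg[batch.edge_dst]
        return Tensor(A)

    def forward(self, batch: ProteinGraphBatch) -> tuple[Tensor, Tensor]:
        """Return hidden (scalar, vector) states for every flat node."""
        s = Tensor(batch.node_scalars)
        V = Tensor(batch.node_vectors)
        s, V = self.embed(s, V)
        agg = self._aggregation_matrix(batch)
        for layer in self.layers:
            s, V = layer(s, V, batch, agg)
        return s, V

    def node_embeddings(self, graph: LocalStructureGraph) -> np.ndarray:
        """Per-node d-dimensional embeddings of one local graph (no grad)."""
        batch = ProteinGraphBatch(
            n_graphs=1,
            node_scalars=graph.node_scalars,
            node_vectors=graph.node_vectors,
            edge_src=graph.edges[:, 0],
            edge_dst=graph.edges[:, 1],
            edge_scalars=graph.edge_scalars,
            edge_vectors=graph.edge_vectors,
            graph_of_node=np.zeros(graph.n_nodes, dtype=np.intp),
            node_residue=graph.nodes,
        )
        with no_grad():
            s, _ = self.forward(batch)
            return self.out_proj(s).data

    def encode_protein(self, structure: ProteinStructure, k: int = DEFAULT_NEIGHBORS) -> np.ndarray:
        """(L, d) array: each residue's mean-pooled local-structure embedding."""
        batch = build_protein_graphs(structure, k)
        with no_grad():
            s, _ = self.forward(batch)
            node_emb = self.out_proj(s).data
        return pool_by_graph(node_emb, batch.graph_of_node, batch.n_graphs)


def pool_by_graph(node_values: np.ndarray, graph_of_node: np.ndarray, n_graphs: int) -> np.ndarray:
    """Mean of node rows within each graph."""
    sums = np.zeros((n_graphs,) + node_values.shape[1:])
    np.add.at(sums, graph_of_node, node_values)
    counts = np.bincount(graph_of_node, minlength=n_graphs).astype(np.float64)
    return sums / counts[:, None]


def pretrain_encoder_denoising(
    structures: list[ProteinStructure],
    encoder: GeometricEncoder,
    noise_sd: float,
    epochs: int,
    rng: np.random.Generator,
    lr: float = 1e-3,
    k: int = DEFAULT_NEIGHBORS,
) -> list[float]:
    """Denoising pretraining: predict per-node C-alpha displacement vectors.

    Each epoch perturbs every structure's C-alphas with fresh isotropic
    Gaussian noise (sd ``noise_sd``; N and C follow their C-alpha rigidly),
    rebuilds the local graphs from the perturbed coordinates, and minimizes
    the mean squared error between the vector head's per-node output and the
    true displacement. Returns the per-epoch mean losses.
    """
    if not structures:
        raise ValueError("pretraining corpus is empty")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    encoder.train()
    opt = AdamW(encoder.parameters(), lr=lr)
    epoch_losses: list[float] = []
    for _ in range(epochs):
        losses = []
        for prot in structures:
            noise = rng.normal(0.0, noise_sd, size=(len(prot), 3))
            perturbed = ProteinStructure(
                id=prot.id,
                sequence=prot.sequence,
                backbone=prot.backbone + noise[:, None, :],
                chain_id=prot.chain_id,
            )
            batch = build_protein_graphs(perturbed, k)
            s, V = encoder.forward(batch)
            _, pred_v = encoder.denoise_head(s, V)
            pred = pred_v.reshape(pred_v.shape[0], 3)
            target = Tensor(noise[batch.node_residue])
            loss = ((pred - target) ** 2.0).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        epoch_losses.append(float(np.mean(losses)))
    encoder.eval()
    return epoch_losses
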