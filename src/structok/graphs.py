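"""Per-residue local-structure graphs with purely geometric features.

Each residue's local structure is the graph over the residue and its k
spatially nearest neighbors (by C-alpha distance). Node and edge features are
rotation-invariant scalars (backbone-dihedral sines/cosines, distance RBFs,
sequence-separation encodings) and rotation-equivariant unit vectors (chain
direction, center-pointing direction, edge displacement). Amino-acid identity
deliberately appears nowhere in any feature, so downstream structure tokens
carry only structural cues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ProteinStructure
from .geometry import backbone_dihedrals, rbf_expand

__all__ = [
    "LocalStructureGraph",
    "ProteinGraphBatch",
    "build_local_graph",
    "build_protein_graphs",
    "NODE_SCALAR_DIM",
    "NODE_VECTOR_DIM",
    "EDGE_SCALAR_DIM",
    "EDGE_VECTOR_DIM",
    "DEFAULT_NEIGHBORS",
]

#: Neighborhood size: each residue's local structure uses its 10 spatially
#: nearest residues.
DEFAULT_NEIGHBORS = 10

_N_RBF = 16
_SEQSEP_CLIP = 32
_SEQSEP_FREQS = (1, 2)

NODE_SCALAR_DIM = 6 + _N_RBF  # phi/psi/omega sin+cos, RBF(dist to center)
NODE_VECTOR_DIM = 2  # unit chain direction, unit center-pointing direction
EDGE_SCALAR_DIM = _N_RBF + 1 + 2 * len(_SEQSEP_FREQS)
EDGE_VECTOR_DIM = 1  # unit displacement


@dataclass
class LocalStructureGraph:
    """Featurized neighborhood graph of one residue."""

    center: int
    nodes: np.ndarray  # residue indices; nodes[0] == center
    node_scalars: np.ndarray  # (n, NODE_SCALAR_DIM)
    node_vectors: np.ndarray  # (n, NODE_VECTOR_DIM, 3)
    edges: np.ndarray  # (E, 2) indices INTO nodes
    edge_scalars: np.ndarray  # (E, EDGE_SCALAR_DIM)
    edge_vectors: np.ndarray  # (E, EDGE_VECTOR_DIM, 3)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


@dataclass
class ProteinGraphBatch:
    """All residues' local graphs of one protein, merged into a disjoint union.

    ``graph_of_node[i]`` maps flat node i to the residue (= graph) it belongs
    to, enabling a single geometric-encoder forward pass per protein.
    """

    n_graphs: int
    node_scalars: np.ndarray
    node_vectors: np.ndarray
    edge_src: np.ndarray  # flat node indices
    edge_dst: np.ndarray
    edge_scalars: np.ndarray
    edge_vectors: np.ndarray
    graph_of_node: np.ndarray
    node_residue: np.ndarray  # original residue index of each flat node


def _seqsep_features(offsets: np.ndarray) -> np.ndarray:
    """Signed sequence-separation encoding: clipped normalized offset plus
    low-frequency sinusoids."""
    d = np.clip(offsets, -_SEQSEP_CLIP, _SEQSEP_CLIP).astype(np.float64)
    feats = [d / _SEQSEP_CLIP]
    for f in _SEQSEP_FREQS:
        feats.append(np.sin(np.pi * f * d / _SEQSEP_CLIP))
        feats.append(np.cos(np.pi * f * d / _SEQSEP_CLIP))
    return np.stack(feats, axis=-1)


def _chain_directions(ca: np.ndarray) -> np.ndarray:
    L = ca.shape[0]
    u = np.zeros((L, 3))
    u[:-1] = ca[1:] - ca[:-1]
    if L >= 2:
        u[-1] = u[-2]
    norms = np.linalg.norm(u, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return u / norms


def _neighbor_order(dist_row: np.ndarray, self_idx: int, k: int) -> np.ndarray:
    """Indices of the k nearest residues to ``self_idx`` (excluded), ties
    broken toward the lower residue index."""
    d = dist_row.copy()
    d[self_idx] = np.inf
    order = np.lexsort((np.arange(len(d)), d))  # distance, then index
    return order[: min(k, len(d) - 1)]


def build_local_graph(
    structure: ProteinStructure, center: int, k: int = DEFAULT_NEIGHBORS
) -> LocalStructureGraph:
    """Build the featurized local graph centered at one residue.

    Nodes are the center plus its ``k`` nearest residues by C-alpha distance
    (clamped to L-1). Edges connect each node to its ``min(4, n-1)`` nearest
    neighbors within the node set.
    """
    L = len(structure)
    if not 0 <= center < L:
        raise IndexError(f"center {center} out of range for L={L}")
    if L < 2:
        raise ValueError("cannot build a local graph for a single-residue protein")
    if k < 1:
        raise ValueError("k must be >= 1")
    ca = structure.ca
    dist = np.linalg.norm(ca[:, None] - ca[None, :], axis=-1)
    neighbors = _neighbor_order(dist[center], center, k)
    nodes = np.concatenate([[center], neighbors]).astype(np.intp)

    dih = backbone_dihedrals(structure.backbone)[nodes]
    node_scalars = np.concatenate(
        [
            np.sin(dih),
            np.cos(dih),
            rbf_expand(dist[center, nodes], _N_RBF),
        ],
        axis=1,
    )
    chain_dir = _chain_directions(ca)[nodes]
    to_center = ca[center] - ca[nodes]
    nrm = np.linalg.norm(to_center, axis=1, keepdims=True)
    nrm[nrm == 0] = 1.0
    node_vectors = np.stack([chain_dir, to_center / nrm], axis=1)

    # internal k-NN edges within the node set
    n = len(nodes)
    k_inner = min(4, n - 1)
    sub = dist[np.ix_(nodes, nodes)]
    edges = []
    for i in range(n):
        nbrs = _neighbor_order(sub[i], i, k_inner)
        for j in nbrs:
            edges.append((i, int(j)))
    edges = np.asarray(edges, dtype=np.intp)
    src, dst = edges[:, 0], edges[:, 1]
    disp = ca[nodes[dst]] - ca[nodes[src]]
    dnorm = np.linalg.norm(disp, axis=1, keepdims=True)
    dnorm[dnorm == 0] = 1.0
    edge_scalars = np.concatenate(
        [
            rbf_expand(dnorm[:, 0], _N_RBF),
            _seqsep_features(nodes[dst].astype(np.int64) - nodes[src].astype(np.int64)),
        ],
        axis=1,
    )
    edge_vectors = (disp / dnorm)[:, None, :]
    return LocalStructureGraph(
        center=center,
        nodes=nodes,
        node_scalars=node_scalars,
        node_vectors=node_vectors,
        edges=edges,
        edge_scalars=edge_scalars,
        edge_vectors=edge_vectors,
    )


def build_protein_graphs(
    structure: ProteinStructure, k: int = DEFAULT_NEIGHBORS
) -> ProteinGraphBatch:
    """Build every residue's local graph and merge them into one batch."""
    L = len(structure)
    graphs = [build_local_graph(structure, i, k) for i in range(L)]
    offsets = np.cumsum([0] + [g.n_nodes for g in graphs])
    node_scalars = np.concatenate([g.node_scalars for g in graphs])
    node_vectors = np.concatenate([g.node_vectors for g in graphs])
    edge_src = np.concatenate([g.edges[:, 0] + off for g, off in zip(graphs, offsets)])
    edge_dst = np.concatenate([g.edges[:, 1] + off for g, off in zip(graphs, offsets)])
    edge_scalars = np.concatenate([g.edge_scalars for g in graphs])
    edge_vectors = np.concatenate([g.edge_vectors for g in graphs])
    graph_of_node = np.concatenate(
        [np.full(g.n_nodes, gi, dtype=np.intp) for gi, g in enumerate(graphs)]
    )
    node_residue = np.concatenate([g.nodes for g in graphs])
    return ProteinGraphBatch(
        n_graphs=L,
        node_scalars=node_scalars,
        node_vectors=node_vectors,
        edge_src=edge_src,
        edge_dst=edge_dst,
        edge_scalars=edge_scalars,
        edge_vectors=edge_vectors,
        graph_of_node=graph_of_node,
        node_residue=node_residue,
    )
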