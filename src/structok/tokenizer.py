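"""Discrete structure tokens: k-means codebook over local-structure embeddings.

A residue's structure token is the index of the nearest codebook centroid to
its mean-pooled local-structure embedding. The codebook is fit with standard
k-means (k-means++ initialization, fixed seed) on an embedding corpus; the
default vocabulary size is 2048.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans

from .core import ProteinStructure, TokenizedProtein, encode_sequence
from .graphs import DEFAULT_NEIGHBORS, LocalStructureGraph
from .gvp import GeometricEncoder, pretrain_encoder_denoising

__all__ = [
    "StructureCodebook",
    "DEFAULT_CODEBOOK_SIZE",
    "encode_local_graph",
    "fit_codebook",
    "assign_structure_tokens",
    "tokenize_protein",
    "StructureTokenizer",
]

#: Default structure vocabulary size.
DEFAULT_CODEBOOK_SIZE = 2048


@dataclass
class StructureCodebook:
    """K centroid vectors defining the discrete structure vocabulary."""

    centroids: np.ndarray  # (K, d)
    fit_metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.centroids = np.asarray(self.centroids, dtype=np.float64)
        if self.centroids.ndim != 2 or self.centroids.shape[0] < 2:
            raise ValueError("codebook needs a (K, d) centroid array with K >= 2")

    @property
    def K(self) -> int:
        return self.centroids.shape[0]

    @property
    def d(self) -> int:
        return self.centroids.shape[1]

    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            centroids=self.centroids,
            metadata=np.array(json.dumps(self.fit_metadata)),
        )

    @classmethod
    def load(cls, path: str | Path) -> "StructureCodebook":
        with np.load(path, allow_pickle=False) as data:
            return cls(
                centroids=data["centroids"],
                fit_metadata=json.loads(str(data["metadata"])),
            )


def encode_local_graph(graph: LocalStructureGraph, encoder) -> np.ndarray:
    """Mean of the per-node encoder outputs: the local-structure embedding.

    ``encoder`` is anything exposing ``node_embeddings(graph) -> (n, d)``.
    """
    node_emb = np.asarray(encoder.node_embeddings(graph))
    if node_emb.shape[0] != graph.n_nodes:
        raise ValueError(
            f"encoder returned {node_emb.shape[0]} node embeddings for a "
            f"{graph.n_nodes}-node graph"
        )
    return node_emb.mean(axis=0)


def fit_codebook(
    embeddings: np.ndarray, K: int = DEFAULT_CODEBOOK_SIZE, seed: int = 0
) -> StructureCodebook:
    """Fit the structure codebook with standard k-means.

    k-means++ initialization with a fixed seed, run to convergence or 300
    iterations; sklearn reseeds empty clusters from distant points.
    """
    embeddings = np.asarray(embeddings, dtype=np.float64)
    M = embeddings.shape[0]
    if M < K:
        raise ValueError(f"need at least K={K} embeddings to fit the codebook, got {M}")
    km = KMeans(n_clusters=K, init="k-means++", n_init=1, max_iter=300, random_state=seed)
    km.fit(embeddings)
    return StructureCodebook(
        centroids=km.cluster_centers_.astype(np.float64),
        fit_metadata={
            "corpus_size": int(M),
            "n_iter": int(km.n_iter_),
            "inertia": float(km.inertia_),
            "seed": int(seed),
        },
    )


def assign_structure_tokens(embeddings: np.ndarray, codebook: StructureCodebook) -> np.ndarray:
    """Nearest-centroid token for each embedding row (ties -> lowest index)."""
    embeddings = np.atleast_2d(np.asarray(embeddings, dtype=np.float64))
    if embeddings.shape[1] != codebook.d:
        raise ValueError(
            f"embedding dimension {embeddings.shape[1]} does not match codebook d={codebook.d}"
        )
    dist = cdist(embeddings, codebook.centroids, metric="euclidean")
    return np.argmin(dist, axis=1).astype(np.int64)


def tokenize_protein(
    structure: ProteinStructure,
    encoder: GeometricEncoder,
    codebook: StructureCodebook,
    k: int = DEFAULT_NEIGHBORS,
) -> TokenizedProtein:
    """Produce parallel residue-token and structure-token sequences."""
    if len(structure) < 2:
        raise ValueError("cannot tokenize a protein with fewer than 2 residues")
    embeddings = encoder.encode_protein(structure, k)
    return TokenizedProtein(
        id=structure.id,
        residue_tokens=encode_sequence(structure.sequence),
        structure_tokens=assign_structure_tokens(embeddings, codebook),
    )


class StructureTokenizer(TransformerMixin, BaseEstimator):
    """Estimator mapping protein structures to discrete token sequences.

    ``fit`` optionally pretrains the geometric encoder by coordinate
    denoising, encodes the corpus, and fits the k-means codebook;
    ``transform`` tokenizes proteins against the fitted codebook.

    Parameters
    ----------
    n_tokens : int
        Structure vocabulary size K.
    k_neighbors : int
        Spatial neighbors per local graph.
    d : int
        Local-structure embedding dimension.
    pretrain_epochs : int
        Denoising pretraining epochs over the fit corpus (0 disables).
    pretrain_noise_sd : float
        Gaussian noise sd (Angstrom) for denoising pretraining.
    seed : int
        Seed for encoder initialization, pretraining noise, and k-means.
    """

    def __init__(
        self,
        n_tokens: int = DEFAULT_CODEBOOK_SIZE,
        k_neighbors: int = DEFAULT_NEIGHBORS,
        d: int = 32,
        pretrain_epochs: int = 2,
        pretrain_noise_sd: float = 0.5,
        seed: int = 0,
    ):
        self.n_tokens = n_tokens
        self.k_neighbors = k_neighbors
        self.d = d
        self.pretrain_epochs = pretrain_epochs
        self.pretrain_noise_sd = pretrain_noise_sd
        self.seed = seed

    def fit(self, X: list[ProteinStructure], y=None) -> "StructureTokenizer":
        self.encoder_ = GeometricEncoder(d=self.d, seed=self.seed)
        if self.pretrain_epochs > 0:
            rng = np.random.default_rng(self.seed)
            self.pretrain_losses_ = pretrain_encoder_denoising(
                X,
                self.encoder_,
                noise_sd=self.pretrain_noise_sd,
                epochs=self.pretrain_epochs,
                rng=rng,
                k=self.k_neighbors,
            )
        embeddings = np.concatenate(
            [self.encoder_.encode_protein(p, self.k_neighbors) for p in X]
        )
        self.codebook_ = fit_codebook(embeddings, K=self.n_tokens, seed=self.seed)
        return self

    def fit_from_artifacts(
        self, codebook: StructureCodebook, encoder_state_path: str | Path | None = None
    ) -> "StructureTokenizer":
        """Adopt a previously fitted codebook (and optional encoder weights)
        instead of refitting; the encoder seed must match the fitting run."""
        self.encoder_ = GeometricEncoder(d=codebook.d, seed=self.seed)
        if encoder_state_path is not None and Path(encoder_state_path).exists():
            with np.load(encoder_state_path, allow_pickle=False) as data:
                self.encoder_.load_state_arrays([data[k] for k in data.files])
        self.codebook_ = codebook
        return self

    def transform(self, X: list[ProteinStructure]) -> list[TokenizedProtein]:
        if not hasattr(self, "codebook_"):
            raise RuntimeError("StructureTokenizer is not fitted")
        return [
            tokenize_protein(p, self.encoder_, self.codebook_, self.k_neighbors) for p in X
        ]
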