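"""Core domain containers: protein structures, label tables, token sequences."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The 20 standard amino acids in alphabetical one-letter order, plus 'X' for
#: anything nonstandard.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AMINO_ACIDS + "X"
AA_TO_INDEX = {a: i for i, a in enumerate(ALPHABET)}

#: Special token ids for the residue stream (appended after the 21 letters).
RESIDUE_PAD = len(ALPHABET)
RESIDUE_MASK = len(ALPHABET) + 1
RESIDUE_VOCAB = len(ALPHABET) + 2  # 21 letters + pad + mask

SPLITS = ("train", "valid", "test")


@dataclass
class ProteinStructure:
    """A single protein chain: sequence plus backbone coordinates.

    Attributes
    ----------
    id : str
        Identifier (PDB id + chain, or synthetic id).
    sequence : str
        Length-L string over the 20 amino-acid letters plus ``X``.
    backbone : numpy.ndarray
        ``(L, 3, 3)`` float array of Angstrom coordinates, atoms ordered
        (N, CA, C) within each residue.
    chain_id : str
        Chain identifier carried from the source file.
    residue_numbers : numpy.ndarray or None
        Original author residue numbering, kept as metadata only; all
        internal indexing is 0-based positional.
    """

    id: str
    sequence: str
    backbone: np.ndarray
    chain_id: str = "A"
    residue_numbers: np.ndarray | None = None

    def __post_init__(self):
        self.backbone = np.asarray(self.backbone, dtype=np.float64)
        if self.backbone.shape != (len(self.sequence), 3, 3):
            raise ValueError(
                f"backbone shape {self.backbone.shape} inconsistent with "
                f"sequence length {len(self.sequence)}"
            )
        if not np.all(np.isfinite(self.backbone)):
            raise ValueError("backbone contains non-finite coordinates")
        bad = set(self.sequence) - set(ALPHABET)
        if bad:
            raise ValueError(f"sequence contains letters outside the 21-letter alphabet: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def ca(self) -> np.ndarray:
        """(L, 3) array of C-alpha coordinates."""
        return self.backbone[:, 1, :]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ProteinStructure":
        """Return a copy under the rigid motion x -> R x + t."""
        R = np.asarray(rotation, dtype=np.float64)
        t = np.asarray(translation, dtype=np.float64)
        coords = self.backbone @ R.T + t
        return ProteinStructure(
            id=self.id,
            sequence=self.sequence,
            backbone=coords,
            chain_id=self.chain_id,
            residue_numbers=self.residue_numbers,
        )


@dataclass
class LabelTable:
    """Binary multi-label annotation table over proteins and ontology terms."""

    protein_ids: list[str]
    term_ids: list[str]
    truth: np.ndarray  # (N, F) in {0, 1}
    split: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.truth = np.asarray(self.truth, dtype=np.int64)
        n, f = self.truth.shape
        if len(self.protein_ids) != n:
            raise ValueError("protein_ids length does not match truth rows")
        if len(self.term_ids) != f:
            raise ValueError("term_ids length does not match truth columns")
        if len(set(self.protein_ids)) != n:
            raise ValueError("duplicate protein ids in label table")
        if not np.isin(self.truth, (0, 1)).all():
            raise ValueError("truth entries must be binary")
        if self.split:
            bad = set(self.split) - set(SPLITS)
            if bad:
                raise ValueError(f"unknown split tags: {sorted(bad)}")

    @property
    def n_proteins(self) -> int:
        return self.truth.shape[0]

    @property
    def n_terms(self) -> int:
        return self.truth.shape[1]

    def subset(self, split: str) -> "LabelTable":
        idx = [i for i, s in enumerate(self.split) if s == split]
        return LabelTable(
            protein_ids=[self.protein_ids[i] for i in idx],
            term_ids=list(self.term_ids),
            truth=self.truth[idx],
            split=[split] * len(idx),
        )


@dataclass
class TokenizedProtein:
    """Parallel residue-token and structure-token sequences for one protein."""

    id: str
    residue_tokens: np.ndarray  # (L,) ints in [0, 21)
    structure_tokens: np.ndarray  # (L,) ints in [0, K)

    def __post_init__(self):
        self.residue_tokens = np.asarray(self.residue_tokens, dtype=np.int64)
        self.structure_tokens = np.asarray(self.structure_tokens, dtype=np.int64)
        if self.residue_tokens.shape != self.structure_tokens.shape:
            raise ValueError("residue and structure token sequences differ in length")

    def __len__(self) -> int:
        return len(self.residue_tokens)


def encode_sequence(sequence: str) -> np.ndarray:
    """Map an amino-acid string to integer residue tokens."""
    try:
        return np.array([AA_TO_INDEX[a] for a in sequence.upper()], dtype=np.int64)
    except KeyError as exc:  # pragma: no cover - guarded upstream
        raise ValueError(f"unknown residue letter {exc}") from exc
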