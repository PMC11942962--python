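"""Reading and writing the standard formats the toolkit touches.

PDB backbones are parsed with biotite; FASTA goes through Biopython; label
tables are tab-separated files handled with pandas. All parsing normalizes
into the containers of :mod:`structok.core`.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .core import SPLITS, LabelTable, ProteinStructure

logger = logging.getLogger(__name__)

__all__ = [
    "read_pdb_backbone",
    "write_pdb_backbone",
    "read_fasta",
    "write_fasta",
    "read_label_table",
    "write_label_table",
]

_BACKBONE_ATOMS = ("N", "CA", "C")

# 3-letter -> 1-letter for the 20 standard residues; selenomethionine is the
# single nonstandard exception mapped to its parent residue.
_THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
    "MSE": "M",
}


def read_pdb_backbone(path: str | Path, chain: str | None = None) -> ProteinStructure:
    """Read one chain's backbone (N, CA, C) from a PDB file.

    Residues missing any backbone atom are dropped with a logged warning.
    Nonstandard residue names map to ``X`` (except MSE -> M). Altlocs are
    resolved by highest occupancy (ties: first in file).

    Parameters
    ----------
    path
        PDB file path.
    chain
        Chain identifier; defaults to the first chain in the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1, altloc="occupancy")
    atoms = atoms[struc.filter_amino_acids(atoms)]
    if atoms.array_length() == 0:
        raise ValueError(f"{path}: no amino-acid residues found")
    chains = list(dict.fromkeys(atoms.chain_id))
    if chain is None:
        chain = chains[0]
    elif chain not in chains:
        raise KeyError(f"{path}: chain {chain!r} not present (have {chains})")
    atoms = atoms[atoms.chain_id == chain]

    backbone_rows = []
    letters = []
    res_numbers = []
    n_dropped = 0
    for res in struc.residue_iter(atoms):
        coords = {}
        for a in res:
            if a.atom_name in _BACKBONE_ATOMS and a.atom_name not in coords:
                coords[a.atom_name] = a.coord
        if len(coords) < 3:
            n_dropped += 1
            continue
        backbone_rows.append([coords[a] for a in _BACKBONE_ATOMS])
        letters.append(_THREE_TO_ONE.get(res.res_name[0], "X"))
        res_numbers.append(int(res.res_id[0]))
    if n_dropped:
        logger.warning(
            "%s chain %s: dropped %d residue(s) with incomplete backbone", path, chain, n_dropped
        )
    if not backbone_rows:
        raise ValueError(f"{path}: chain {chain!r} has no residue with a complete N/CA/C backbone")
    return ProteinStructure(
        id=path.stem,
        sequence="".join(letters),
        backbone=np.asarray(backbone_rows, dtype=np.float64),
        chain_id=str(chain),
        residue_numbers=np.asarray(res_numbers, dtype=np.int64),
    )


def write_pdb_backbone(structure: ProteinStructure, path: str | Path) -> None:
    """Write a backbone-only PDB file (inverse of :func:`read_pdb_backbone`)."""
    one_to_three = {v: k for k, v in _THREE_TO_ONE.items() if k != "MSE"}
    one_to_three["X"] = "UNK"
    L = len(structure)
    atoms = struc.AtomArray(L * 3)
    for i in range(L):
        for j, name in enumerate(_BACKBONE_ATOMS):
            k = i * 3 + j
            atoms.coord[k] = structure.backbone[i, j]
            atoms.chain_id[k] = structure.chain_id
            atoms.res_id[k] = (
                int(structure.residue_numbers[i]) if structure.residue_numbers is not None else i + 1
            )
            atoms.res_name[k] = one_to_three[structure.sequence[i]]
            atoms.atom_name[k] = name
            atoms.element[k] = name[0]
    atoms.hetero[:] = False
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, uppercase sequence) pairs, order preserved."""
    path = Path(path)
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"{path}: empty or invalid FASTA")
    ids = [r[0] for r in records]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValueError(f"{path}: duplicate FASTA ids: {dupes}")
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    """Write (id, sequence) pairs as FASTA with a configurable wrap width."""
    seq_records = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    with open(path, "w") as fh:
        FastaWriter(fh, wrap=width).write_file(seq_records)


def read_label_table(path: str | Path) -> LabelTable:
    """Read a tab-separated label table.

    Expected header: ``protein_id``, ``split``, then one column per term.
    Cells must be 0/1; split tags must be train/valid/test.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("protein_id", "split"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    term_ids = [c for c in df.columns if c not in ("protein_id", "split")]
    values = df[term_ids].to_numpy()
    if not np.isin(values, ("0", "1")).all():
        bad = sorted(set(values[~np.isin(values, ("0", "1"))].ravel()))
        raise ValueError(f"{path}: non-binary label cell value(s): {bad}")
    splits = df["split"].tolist()
    bad_splits = sorted(set(splits) - set(SPLITS))
    if bad_splits:
        raise ValueError(f"{path}: unknown split tag(s): {bad_splits}")
    return LabelTable(
        protein_ids=df["protein_id"].tolist(),
        term_ids=term_ids,
        truth=values.astype(np.int64),
        split=splits,
    )


def write_label_table(table: LabelTable, path: str | Path) -> None:
    df = pd.DataFrame(table.truth, columns=table.term_ids)
    df.insert(0, "split", table.split)
    df.insert(0, "protein_id", table.protein_ids)
    df.to_csv(path, sep="\t", index=False)
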