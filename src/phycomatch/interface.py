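"""Inter-dimer contact interfaces in predicted hexamer structures.

Given a predicted (αβ)₃ structure and a grouping of its chains into αβ
dimers, this module finds the residue pairs from different dimers whose
heavy atoms approach within a distance cutoff (3 Å by default), summarizes
structure-prediction confidence (PAE, pLDDT) over that interface, and
projects the interface residues onto multiple-alignment columns so their
conservation across strains can be scored.

Structures are read with gemmi (PDB or mmCIF); PAE matrices from the JSON
confidence files that structure predictors emit, in either the
matrix-of-rows or the flat paired-list dialect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence, Union

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .conservation import MultipleAlignment, position_to_column

__all__ = [
    "ContactPair",
    "ConfidenceSummary",
    "read_structure",
    "chain_sequence",
    "residue_index",
    "find_contacts",
    "interface_residues",
    "read_pae_json",
    "plddt_from_structure",
    "summarize_confidence",
    "derive_interface_columns",
]


@dataclass(frozen=True)
class ContactPair:
    """A cross-dimer residue pair with its minimum heavy-atom distance (Å).

    Canonically oriented: (chain_a, resnum_a) sorts before (chain_b,
    resnum_b), so each unordered pair appears exactly once.
    """

    chain_a: str
    resnum_a: int
    resname_a: str
    chain_b: str
    resnum_b: int
    resname_b: str
    distance: float


@dataclass(frozen=True)
class ConfidenceSummary:
    """Prediction confidence over a contact interface."""

    mean_interface_pae: float
    mean_interface_plddt: float
    n_contacts: int
    n_interface_residues: int


def read_structure(path: Union[str, Path]) -> gemmi.Structure:
    """Read a PDB or mmCIF structure and set up entities."""
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    return st


def _heavy_atoms(structure: gemmi.Structure, include_hetero: bool):
    """Yield (chain id, resnum, resname, xyz) for every heavy atom of model 1."""
    model = structure[0]
    for chain in model:
        for residue in chain:
            info = gemmi.find_tabulated_residue(residue.name)
            is_aa = info is not None and info.is_amino_acid()
            if not is_aa and not include_hetero:
                continue
            if residue.is_water():
                continue
            for atom in residue:
                if atom.element == gemmi.Element("H") or atom.element == gemmi.Element("D"):
                    continue
                pos = atom.pos
                yield (chain.name, residue.seqid.num, residue.name,
                       (pos.x, pos.y, pos.z))


def find_contacts(
    structure: gemmi.Structure,
    grouping: Mapping[str, int],
    cutoff: float = 3.0,
    include_hetero: bool = False,
) -> list[ContactPair]:
    """Residue pairs across dimer groups with min heavy-atom distance ≤ cutoff.

    ``grouping`` maps every analyzed chain id to its dimer index; a chain
    present in the structure but absent from the grouping is an error.
    Hydrogens are always excluded; non-amino-acid residues are excluded
    unless ``include_hetero``.  Output is sorted by
    (chain_a, resnum_a, chain_b, resnum_b).
    """
    if len(set(grouping.values())) < 2:
        raise ValueError("grouping must define at least two dimer groups")
    records = list(_heavy_atoms(structure, include_hetero))
    missing = sorted({r[0] for r in records} - set(grouping))
    if missing:
        raise ValueError(f"chains not covered by the dimer grouping: {missing}")
    if not records:
        return []
    coords = np.array([r[3] for r in records])
    tree = cKDTree(coords)
    best: dict[tuple, tuple[float, str, str]] = {}
    for i, j in tree.query_pairs(cutoff):
        ca, ra, na, _ = records[i]
        cb, rb, nb, _ = records[j]
        if grouping[ca] == grouping[cb]:
            continue
        if (cb, rb) < (ca, ra):
            (ca, ra, na), (cb, rb, nb) = (cb, rb, nb), (ca, ra, na)
        d = float(np.linalg.norm(coords[i] - coords[j]))
        key = (ca, ra, cb, rb)
        if key not in best or d < best[key][0]:
            best[key] = (d, na, nb)
    out = [
        ContactPair(ca, ra, na, cb, rb, nb, d)
        for (ca, ra, cb, rb), (d, na, nb) in best.items()
    ]
    out.sort(key=lambda c: (c.chain_a, c.resnum_a, c.chain_b, c.resnum_b))
    return out


def interface_residues(
    contacts: Sequence[ContactPair],
    grouping: Mapping[str, int],
) -> dict[int, set[tuple[str, int]]]:
    """Union of contacting residues, keyed by dimer group index."""
    out: dict[int, set[tuple[str, int]]] = {}
    for c in contacts:
        out.setdefault(grouping[c.chain_a], set()).add((c.chain_a, c.resnum_a))
        out.setdefault(grouping[c.chain_b], set()).add((c.chain_b, c.resnum_b))
    return out


def read_pae_json(path: Union[str, Path]) -> np.ndarray:
    """Read a predicted-aligned-error matrix from JSON.

    Accepts the common dialects: ``{"predicted_aligned_error": [[...]]}``
    (possibly wrapped in a one-element list), ``{"pae": [[...]]}``, and the
    flat paired-list form ``{"residue1": [...], "residue2": [...],
    "distance": [...]}``.
    """
    data = json.loads(Path(path).read_text())
    if isinstance(data, list):
        if not data:
            raise ValueError("empty PAE JSON")
        data = data[0]
    for key in ("predicted_aligned_error", "pae"):
        if key in data:
            return np.asarray(data[key], dtype=float)
    if {"residue1", "residue2", "distance"} <= set(data):
        r1 = np.asarray(data["residue1"], dtype=int)
        r2 = np.asarray(data["residue2"], dtype=int)
        d = np.asarray(data["distance"], dtype=float)
        n = int(max(r1.max(), r2.max()))
        mat = np.zeros((n, n))
        mat[r1 - 1, r2 - 1] = d
        return mat
    raise ValueError("unrecognized PAE JSON dialect")


def residue_index(structure: gemmi.Structure,
                  chains: Sequence[str] | None = None) -> dict[tuple[str, int], int]:
    """(chain, resnum) → 0-based row index into PAE/pLDDT arrays.

    Follows file order of the polymer residues, the convention the
    prediction confidence files use.
    """
    idx: dict[tuple[str, int], int] = {}
    n = 0
    for chain in structure[0]:
        if chains is not None and chain.name not in chains:
            continue
        for residue in chain:
            info = gemmi.find_tabulated_residue(residue.name)
            if info is None or not info.is_amino_acid():
                continue
            idx[(chain.name, residue.seqid.num)] = n
            n += 1
    return idx


def plddt_from_structure(structure: gemmi.Structure,
                         chains: Sequence[str] | None = None) -> np.ndarray:
    """Per-residue pLDDT from B-factor columns (predictor convention)."""
    vals = []
    for chain in structure[0]:
        if chains is not None and chain.name not in chains:
            continue
        for residue in chain:
            info = gemmi.find_tabulated_residue(residue.name)
            if info is None or not info.is_amino_acid():
                continue
            vals.append(float(np.mean([a.b_iso for a in residue])))
    return np.asarray(vals)


def summarize_confidence(
    pae: np.ndarray,
    plddt: np.ndarray,
    interface_sets: Mapping[int, set[tuple[str, int]]],
    index: Mapping[tuple[str, int], int],
    n_contacts: int | None = None,
) -> ConfidenceSummary:
    """Mean PAE over cross-group interface residue pairs and mean pLDDT.

    PAE is asymmetric: both PAE[i, j] and PAE[j, i] enter the mean for every
    cross-group pair of interface residues.  pLDDT is averaged over the
    union of interface residues.
    """
    pae = np.asarray(pae, dtype=float)
    if pae.ndim != 2 or pae.shape[0] != pae.shape[1]:
        raise ValueError("PAE matrix must be square")
    groups = sorted(interface_sets)
    residues = [(g, r) for g in groups for r in sorted(interface_sets[g])]
    if not residues:
        raise ValueError(
            "empty interface: no contact residues (check the distance cutoff)"
        )
    pae_vals = []
    for gi, ri in residues:
        for gj, rj in residues:
            if gi < gj:
                i, j = index[ri], index[rj]
                pae_vals.append(pae[i, j])
                pae_vals.append(pae[j, i])
    all_res = {r for g in groups for r in interface_sets[g]}
    plddt_vals = [float(plddt[index[r]]) for r in all_res]
    return ConfidenceSummary(
        mean_interface_pae=float(np.mean(pae_vals)),
        mean_interface_plddt=float(np.mean(plddt_vals)),
        n_contacts=len(pae_vals) // 2 if n_contacts is None else n_contacts,
        n_interface_residues=len(all_res),
    )


def chain_sequence(structure: gemmi.Structure, chain_id: str) -> str:
    """One-letter amino-acid sequence of a chain, in residue order."""
    for chain in structure[0]:
        if chain.name == chain_id:
            letters = []
            for residue in chain:
                info = gemmi.find_tabulated_residue(residue.name)
                if info is None or not info.is_amino_acid():
                    continue
                letters.append(info.one_letter_code.upper())
            return "".join(letters)
    raise KeyError(f"no chain {chain_id!r} in structure")


def derive_interface_columns(
    structure: gemmi.Structure,
    grouping: Mapping[str, int],
    alignment: MultipleAlignment,
    chain_to_row: Mapping[str, str],
    cutoff: float = 3.0,
) -> dict[str, list[int]]:
    """Alignment columns of the cross-dimer interface residues, per chain.

    Each analyzed chain is mapped to an alignment row; the chain's sequence
    must equal the row's ungapped sequence (checked residue by residue).
    Composes contact finding, interface-residue collection and the inverse
    column↔position map.  Returns 1-based columns, sorted, per chain id.
    """
    seq_pos: dict[str, dict[int, int]] = {}
    for chain_id, row_id in chain_to_row.items():
        chain_seq = chain_sequence(structure, chain_id)
        row_seq = alignment.ungapped(row_id)
        for k, (a, b) in enumerate(zip(chain_seq, row_seq), start=1):
            if a != b:
                raise ValueError(
                    f"chain {chain_id} residue {k} ({a}) does not match "
                    f"alignment row {row_id!r} ({b})"
                )
        if len(chain_seq) != len(row_seq):
            raise ValueError(
                f"chain {chain_id} length {len(chain_seq)} != ungapped row "
                f"{row_id!r} length {len(row_seq)}"
            )
        # residue seqid → 1-based sequence position, in chain order
        positions = {}
        n = 0
        for chain in structure[0]:
            if chain.name != chain_id:
                continue
            for residue in chain:
                info = gemmi.find_tabulated_residue(residue.name)
                if info is None or not info.is_amino_acid():
                    continue
                n += 1
                positions[residue.seqid.num] = n
        seq_pos[chain_id] = positions

    contacts = find_contacts(structure, grouping, cutoff)
    residues = interface_residues(contacts, grouping)
    out: dict[str, list[int]] = {}
    for group_set in residues.values():
        for chain_id, resnum in group_set:
            if chain_id not in chain_to_row:
                continue
            pos = seq_pos[chain_id][resnum]
            col = position_to_column(alignment, chain_to_row[chain_id], pos)
            out.setdefault(chain_id, []).append(col)
    return {c: sorted(set(cols)) for c, cols in out.items()}
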