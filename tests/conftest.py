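"""Shared fixtures: toy alignments and programmatically built structures."""

from __future__ import annotations

import gemmi
import numpy as np
import pytest
from hypothesis import settings

from phycomatch.conservation import MultipleAlignment

settings.register_profile("deterministic", derandomize=True, deadline=None,
                          database=None)
settings.load_profile("deterministic")

# Independent copy of the standard average residue masses (test oracle;
# deliberately not imported from the package).
ORACLE_RESIDUE_MASSES = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
ORACLE_WATER = 18.0153


def oracle_chain_mass(residues: str) -> float:
    """Reference residue-sum mass: plain left-to-right accumulation."""
    total = ORACLE_WATER
    for r in residues:
        total += ORACLE_RESIDUE_MASSES[r]
    return total


@pytest.fixture
def toy_alignment() -> MultipleAlignment:
    """4 sequences x 6 columns with gaps; used against pair-count oracles."""
    return MultipleAlignment(
        ids=("s1", "s2", "s3", "s4"),
        rows=("MAK-LV",
              "MAR-LI",
              "M-KQLV",
              "MAKQ-V"),
    )


def build_structure(residues):
    """Build a gemmi.Structure from
    [(chain_id, resnum, resname, [(atom_name, element, (x, y, z)), ...]), ...].
    """
    st = gemmi.Structure()
    st.name = "toy"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for chain_id, resnum, resname, atoms in residues:
        if chain_id not in chains:
            chains[chain_id] = gemmi.Chain(chain_id)
        res = gemmi.Residue()
        res.name = resname
        res.seqid = gemmi.SeqId(resnum, " ")
        for name, element, (x, y, z) in atoms:
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(element)
            atom.pos = gemmi.Position(x, y, z)
            res.add_atom(atom)
        chains[chain_id].add_residue(res)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    return st


@pytest.fixture
def two_group_structure():
    """Two chains, one residue pair at 2.5 A across groups, one at 3.5 A."""
    return build_structure([
        ("A", 1, "ALA", [("CA", "C", (0.0, 0.0, 0.0))]),
        ("A", 2, "GLY", [("CA", "C", (0.0, 10.0, 0.0))]),
        ("B", 1, "SER", [("CA", "C", (2.5, 0.0, 0.0))]),
        ("B", 2, "VAL", [("CA", "C", (3.5, 10.0, 0.0))]),
    ])


def random_structure(rng: np.random.Generator, n_per_chain: int = 10,
                     spread: float = 8.0):
    """Two-chain random-coordinate structure for brute-force contact checks."""
    residues = []
    names = ["ALA", "GLY", "SER", "LEU", "THR"]
    for chain_id, offset in (("A", 0.0), ("B", 2.0)):
        for i in range(1, n_per_chain + 1):
            atoms = []
            for j in range(3):
                xyz = tuple(rng.uniform(0, spread, size=3) + offset)
                atoms.append((f"C{j}", "C", xyz))
            residues.append((chain_id, i, names[i % len(names)], atoms))
    return build_structure(residues)


def brute_force_contacts(structure, grouping, cutoff):
    """O(n^2) oracle: min heavy-atom distance per cross-group residue pair."""
    atoms = []
    for chain in structure[0]:
        for res in chain:
            for atom in res:
                if atom.element.name in ("H", "D"):
                    continue
                atoms.append((chain.name, res.seqid.num,
                              np.array([atom.pos.x, atom.pos.y, atom.pos.z])))
    best = {}
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            ca, ra, pa = atoms[i]
            cb, rb, pb = atoms[j]
            if grouping[ca] == grouping[cb]:
                continue
            d = float(np.linalg.norm(pa - pb))
            if d > cutoff:
                continue
            key = tuple(sorted([(ca, ra), (cb, rb)]))
            if key not in best or d < best[key]:
                best[key] = d
    return best
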