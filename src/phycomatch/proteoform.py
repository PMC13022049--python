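"""Neutral average masses of phycobiliprotein subunits.

Phycobiliprotein α and β chains carry covalently attached phycocyanobilin
chromophores and, on β chains, a conserved N4-methylasparagine.  Together
with partial loss of the initiator methionine these post-translational
modifications shift each subunit's neutral mass away from the bare
residue-chain mass.  This module computes those proteoform masses from
sequence using average (not monoisotopic) residue masses: at the mass
resolution of native MS of ~100 kDa complexes only the average-mass
envelope is observed.

Masses are in daltons throughout.  Sequence positions are 1-based.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Union

from Bio import SeqIO

__all__ = [
    "Family",
    "Chain",
    "MetLoss",
    "SubunitSequence",
    "PTMRule",
    "MassConstants",
    "ProteoformMass",
    "AVERAGE_RESIDUE_MASSES",
    "DEFAULT_CONSTANTS",
    "residue_chain_mass",
    "default_rules",
    "apply_ptm_rules",
    "read_subunit_fasta",
    "write_subunit_fasta",
]

#: Standard average residue (amino-acid minus water) masses in Da.
AVERAGE_RESIDUE_MASSES: Mapping[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

_VALID_RESIDUES = frozenset(AVERAGE_RESIDUE_MASSES)


class Family(str, Enum):
    """Phycobiliprotein family: allophycocyanin (core) or phycocyanin (rod)."""

    APC = "APC"
    PC = "PC"


class Chain(str, Enum):
    """Subunit chain type; ``alphaB`` is the ApcD variant α chain."""

    ALPHA = "alpha"
    ALPHA_B = "alphaB"
    BETA = "beta"


class MetLoss(str, Enum):
    """Initiator-methionine processing state for a rule."""

    NEVER = "never"
    ALWAYS = "always"
    VARIABLE = "variable"


@dataclass(frozen=True)
class SubunitSequence:
    """One subunit amino-acid sequence from one strain.

    Parameters
    ----------
    strain_id
        Free-text strain label.
    family
        ``Family.APC`` or ``Family.PC``.
    chain
        ``alpha``, ``alphaB`` or ``beta``.
    residues
        One-letter amino-acid sequence (20 canonical codes, length >= 1).
    """

    strain_id: str
    family: Family
    chain: Chain
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", Family(self.family))
        object.__setattr__(self, "chain", Chain(self.chain))
        if len(self.residues) < 1:
            raise ValueError(
                f"{self.strain_id}/{self.chain.value}: empty sequence"
            )
        _check_residues(self.residues)

    @property
    def label(self) -> str:
        return f"{self.strain_id}|{self.family.value}|{self.chain.value}"


def _check_residues(residues: str) -> None:
    for i, letter in enumerate(residues, start=1):
        if letter not in _VALID_RESIDUES:
            raise ValueError(
                f"unknown residue {letter!r} at position {i}; expected one of "
                f"the 20 canonical one-letter codes"
            )


@dataclass(frozen=True)
class PTMRule:
    """Post-translational modification rule for one family/chain combination.

    ``met_loss`` controls initiator-Met handling: ``never`` and ``always``
    yield one proteoform, ``variable`` yields the with- and without-Met pair
    (partial N-terminal processing).
    """

    n_chromophores: int
    met_loss: MetLoss
    n_methylations: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "met_loss", MetLoss(self.met_loss))
        if self.n_chromophores < 0 or self.n_methylations < 0:
            raise ValueError("PTM counts must be >= 0")


@dataclass(frozen=True)
class MassConstants:
    """Mass deltas (Da) used by the proteoform mass engine.

    Defaults follow common native-MS practice for phycobiliproteins:
    +586.7 Da per covalently bound phycocyanobilin, −131.2 Da per lost
    initiator methionine, +14.0 Da per asparagine methylation.
    """

    chromophore_mass: float = 586.7
    met_loss_mass: float = 131.2
    methylation_mass: float = 14.0
    water_mass: float = 18.0153
    proton_mass: float = 1.00728
    residue_masses: Mapping[str, float] = field(
        default_factory=lambda: dict(AVERAGE_RESIDUE_MASSES)
    )

    def __post_init__(self) -> None:
        for name in ("chromophore_mass", "met_loss_mass", "methylation_mass",
                     "water_mass", "proton_mass"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if set(self.residue_masses) != _VALID_RESIDUES:
            raise ValueError("residue_masses must cover exactly the 20 canonical codes")
        if any(m <= 0 for m in self.residue_masses.values()):
            raise ValueError("residue masses must be > 0")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "MassConstants":
        """Load overrides from a JSON object; missing keys keep defaults."""
        data = json.loads(Path(path).read_text())
        base = cls()
        if "residue_masses" in data:
            merged = dict(base.residue_masses)
            merged.update(data.pop("residue_masses"))
            base = replace(base, residue_masses=merged)
        return replace(base, **data)


DEFAULT_CONSTANTS = MassConstants()


@dataclass(frozen=True)
class ProteoformMass:
    """A single neutral proteoform mass derived from one subunit sequence."""

    source: SubunitSequence
    met_lost: bool
    mass: float

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("proteoform mass must be > 0")


def residue_chain_mass(
    seq: Union[SubunitSequence, str],
    constants: MassConstants = DEFAULT_CONSTANTS,
) -> float:
    """Unmodified average mass of the intact chain: residue sum + one water.

    Accepts a :class:`SubunitSequence` or a bare one-letter string (the
    empty string returns the mass of water).  Uses compensated summation so
    the result is independent of accumulation order to well below 1e-6 Da.
    """
    residues = seq.residues if isinstance(seq, SubunitSequence) else seq
    _check_residues(residues)
    table = constants.residue_masses
    return math.fsum(table[r] for r in residues) + constants.water_mass


#: PTM rule table by (family, chain).  The ApcD-type alphaB chain follows
#: the ordinary APC α rule (one bilin, processed Met).
_RULE_TABLE: Mapping[tuple[Family, Chain], PTMRule] = {
    (Family.APC, Chain.ALPHA): PTMRule(1, MetLoss.ALWAYS, 0),
    (Family.APC, Chain.ALPHA_B): PTMRule(1, MetLoss.ALWAYS, 0),
    (Family.APC, Chain.BETA): PTMRule(1, MetLoss.NEVER, 1),
    (Family.PC, Chain.ALPHA): PTMRule(1, MetLoss.NEVER, 0),
    (Family.PC, Chain.BETA): PTMRule(2, MetLoss.VARIABLE, 1),
}


def default_rules(family: Union[Family, str], chain: Union[Chain, str]) -> PTMRule:
    """PTM rule for a family/chain combination.

    APC α (and αB): 1 bilin, Met always lost.  APC β: 1 bilin, +1
    methylation, Met retained.  PC α: 1 bilin, Met retained.  PC β:
    2 bilins, +1 methylation, 0–1 Met losses (both forms observed).
    """
    key = (Family(family), Chain(chain))
    try:
        return _RULE_TABLE[key]
    except KeyError:
        known = ", ".join(f"{f.value}/{c.value}" for f, c in _RULE_TABLE)
        raise ValueError(
            f"no PTM rule for {key[0].value}/{key[1].value}; known: {known}"
        ) from None


def apply_ptm_rules(
    seq: SubunitSequence,
    rule: PTMRule | None = None,
    constants: MassConstants = DEFAULT_CONSTANTS,
) -> list[ProteoformMass]:
    """Expand a sequence into its proteoform masses under a PTM rule.

    Returns one proteoform for ``never``/``always`` Met handling and two
    (with and without the initiator Met) for ``variable``.  ``rule=None``
    looks up :func:`default_rules` for the sequence's family/chain.
    """
    if rule is None:
        rule = default_rules(seq.family, seq.chain)
    if rule.met_loss is not MetLoss.NEVER and not seq.residues.startswith("M"):
        raise ValueError(
            f"{seq.strain_id}/{seq.chain.value}: Met-loss rule "
            f"({rule.met_loss.value}) requires a leading methionine"
        )
    base = (
        residue_chain_mass(seq, constants)
        + rule.n_chromophores * constants.chromophore_mass
        + rule.n_methylations * constants.methylation_mass
    )
    met_states = {
        MetLoss.NEVER: (False,),
        MetLoss.ALWAYS: (True,),
        MetLoss.VARIABLE: (False, True),
    }[rule.met_loss]
    return [
        ProteoformMass(
            source=seq,
            met_lost=lost,
            mass=base - (constants.met_loss_mass if lost else 0.0),
        )
        for lost in met_states
    ]


def read_subunit_fasta(path: Union[str, Path]) -> list[SubunitSequence]:
    """Read subunit sequences from FASTA with ``>strain_id|family|chain`` headers."""
    out = []
    for record in SeqIO.parse(str(path), "fasta"):
        parts = record.id.split("|")
        if len(parts) != 3:
            raise ValueError(
                f"FASTA header {record.id!r} must be 'strain_id|family|chain'"
            )
        strain, family, chain = parts
        out.append(SubunitSequence(strain, Family(family), Chain(chain),
                                   str(record.seq).upper()))
    return out


def write_subunit_fasta(seqs: Iterable[SubunitSequence], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.label}\n")
            for i in range(0, len(s.residues), 60):
                fh.write(s.residues[i:i + 60] + "\n")
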