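"""Candidate (αβ)ₙ complex compositions and their theoretical mass ladders.

Phycobiliproteins assemble from αβ dimer building blocks into donut-shaped
(αβ)₃ hexamers.  When extracts from several strains are mixed, heterologous
hexamers carrying dimers from different strains can form — but only within
a family (APC with APC, PC with PC) and only from intact αβ dimers.  This
module enumerates every candidate composition over a strain set (pure and
heterologous), expands variable Met-loss proteoforms into the mass ladder
each composition can present, and generates negative-control "decoy"
compositions (cross-family hexamers, cross-strain αβ dimers) that the
assignment stage should reject.

A non-covalent assembly carries exactly the summed mass of its subunits.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

from .proteoform import (
    Chain,
    Family,
    MassConstants,
    DEFAULT_CONSTANTS,
    ProteoformMass,
    PTMRule,
    SubunitSequence,
    apply_ptm_rules,
)

__all__ = [
    "DimerUnit",
    "ComplexComposition",
    "TheoreticalComplex",
    "ProteoformRegistry",
    "enumerate_compositions",
    "composition_mass_variants",
    "decoy_compositions",
    "candidate_table",
    "write_candidates_csv",
]

MASS_DEDUP_TOL = 1e-6  # Da; theoretical masses closer than this are one species


@dataclass(frozen=True, order=True)
class DimerUnit:
    """One αβ dimer building block.

    ``beta_strain_id`` defaults to the α strain; a differing value denotes a
    cross-strain αβ decoy dimer (never observed in the mixing experiments).
    """

    family: Family
    strain_id: str
    beta_strain_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", Family(self.family))
        if not self.beta_strain_id:
            object.__setattr__(self, "beta_strain_id", self.strain_id)

    @property
    def is_cross_strain(self) -> bool:
        return self.beta_strain_id != self.strain_id

    @property
    def label(self) -> str:
        if self.is_cross_strain:
            return f"{self.strain_id}*{self.beta_strain_id}"
        return self.strain_id


@dataclass(frozen=True)
class ComplexComposition:
    """A multiset of αβ dimer units; 1 unit = dimer, 3 units = hexamer.

    Units are stored sorted so equal multisets compare (and hash) equal
    regardless of construction order.  Compositions mixing families or
    using cross-strain dimers must be flagged ``is_decoy``.
    """

    units: tuple[DimerUnit, ...]
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not self.units:
            raise ValueError("composition needs at least one dimer unit")
        object.__setattr__(self, "units", tuple(sorted(self.units)))
        families = {u.family for u in self.units}
        cross = any(u.is_cross_strain for u in self.units)
        if (len(families) > 1 or cross) and not self.is_decoy:
            raise ValueError(
                "cross-family or cross-strain compositions must be decoys"
            )

    @property
    def n_dimers(self) -> int:
        return len(self.units)

    @property
    def families(self) -> frozenset[Family]:
        return frozenset(u.family for u in self.units)

    @property
    def label(self) -> str:
        """Human-readable label, e.g. ``PC:2xStrainA+1xStrainB``."""
        counts = Counter(self.units)
        parts = "+".join(
            f"{n}x{u.label}" for u, n in sorted(counts.items(), key=lambda kv: kv[0])
        )
        fams = "/".join(sorted(f.value for f in self.families))
        tag = " [decoy]" if self.is_decoy else ""
        return f"{fams}:{parts}{tag}"


@dataclass(frozen=True)
class TheoreticalComplex:
    """One neutral mass of a composition, for a specific Met-loss variant.

    ``variant_key`` records per-unit (α Met lost, β Met lost) flags in unit
    order; ``n_met_lost`` is their total.
    """

    composition: ComplexComposition
    variant_key: tuple[tuple[bool, bool], ...]
    neutral_mass: float

    @property
    def n_met_lost(self) -> int:
        return sum(a + b for a, b in self.variant_key)

    @property
    def label(self) -> str:
        return f"{self.composition.label}|-{self.n_met_lost}Met"


class ProteoformRegistry:
    """Lookup of proteoform masses by (strain, family, chain).

    Built from :class:`SubunitSequence` objects; the default PTM rules are
    applied unless a per-(family, chain) override is supplied.
    """

    def __init__(self) -> None:
        self._forms: dict[tuple[str, Family, Chain], tuple[ProteoformMass, ...]] = {}
        self._sequences: dict[tuple[str, Family, Chain], SubunitSequence] = {}

    @classmethod
    def from_sequences(
        cls,
        sequences: Iterable[SubunitSequence],
        constants: MassConstants = DEFAULT_CONSTANTS,
        rules: Mapping[tuple[Family, Chain], PTMRule] | None = None,
    ) -> "ProteoformRegistry":
        reg = cls()
        for seq in sequences:
            rule = rules.get((seq.family, seq.chain)) if rules else None
            forms = apply_ptm_rules(seq, rule, constants)
            key = (seq.strain_id, seq.family, seq.chain)
            if key in reg._forms:
                raise ValueError(f"duplicate sequence for {seq.label}")
            reg._forms[key] = tuple(forms)
            reg._sequences[key] = seq
        return reg

    def forms(self, strain_id: str, family: Family, chain: Chain) -> tuple[ProteoformMass, ...]:
        key = (strain_id, Family(family), Chain(chain))
        try:
            return self._forms[key]
        except KeyError:
            raise KeyError(
                f"no proteoforms for {strain_id}|{Family(family).value}|{Chain(chain).value}"
            ) from None

    def has(self, strain_id: str, family: Family, chain: Chain) -> bool:
        return (strain_id, Family(family), Chain(chain)) in self._forms

    def strains(self, family: Family | None = None) -> list[str]:
        """Strains with both an α and a β chain loaded (for ``family`` if given)."""
        fams = [Family(family)] if family else list(Family)
        out = set()
        for f in fams:
            for strain in {k[0] for k in self._forms}:
                if self.has(strain, f, Chain.ALPHA) and self.has(strain, f, Chain.BETA):
                    out.add(strain)
        return sorted(out)

    def families_of(self, strain_id: str) -> list[Family]:
        return sorted(
            {f for f in Family
             if self.has(strain_id, f, Chain.ALPHA) and self.has(strain_id, f, Chain.BETA)},
            key=lambda f: f.value,
        )


def _check_strains(registry: ProteoformRegistry | None,
                   strains: Sequence[str], family: Family) -> None:
    if registry is None:
        return
    for strain in strains:
        for chain in (Chain.ALPHA, Chain.BETA):
            if not registry.has(strain, family, chain):
                raise ValueError(
                    f"strain {strain!r} lacks a {family.value} {chain.value} sequence"
                )


def enumerate_compositions(
    strains: Sequence[str],
    family: Union[Family, str],
    n_dimers: int,
    cross_family: bool = False,
    registry: ProteoformRegistry | None = None,
) -> list[ComplexComposition]:
    """All multisets of ``n_dimers`` pure αβ dimers over ``strains``.

    Single-family by default (C(k+n−1, n) compositions for k strains).
    With ``cross_family=True`` the mixed APC/PC multisets are appended,
    flagged as decoys — such hexamers are not observed experimentally and
    serve as negative controls.
    """
    if not strains:
        raise ValueError("need at least one strain")
    if len(set(strains)) != len(strains):
        raise ValueError("duplicate strain ids")
    if n_dimers < 1:
        raise ValueError("n_dimers must be >= 1")
    family = Family(family)
    _check_strains(registry, strains, family)

    units = sorted(DimerUnit(family, s) for s in strains)
    out = [
        ComplexComposition(combo)
        for combo in itertools.combinations_with_replacement(units, n_dimers)
    ]
    if cross_family:
        other = Family.PC if family is Family.APC else Family.APC
        _check_strains(registry, strains, other)
        all_units = sorted(units + [DimerUnit(other, s) for s in strains])
        for combo in itertools.combinations_with_replacement(all_units, n_dimers):
            if len({u.family for u in combo}) > 1:
                out.append(ComplexComposition(combo, is_decoy=True))
    return out


def composition_mass_variants(
    comp: ComplexComposition,
    registry: ProteoformRegistry,
) -> list[TheoreticalComplex]:
    """Expand a composition into its distinct theoretical neutral masses.

    Variable Met-loss on constituent chains yields a ladder of masses
    (spacing = one Met-loss mass); combinations summing to the same mass
    are merged.  Sorted ascending by mass.
    """
    per_unit_choices = []
    for unit in comp.units:
        alphas = registry.forms(unit.strain_id, unit.family, Chain.ALPHA)
        betas = registry.forms(unit.beta_strain_id, unit.family, Chain.BETA)
        per_unit_choices.append(
            [(a, b) for a in alphas for b in betas]
        )
    variants: list[TheoreticalComplex] = []
    for choice in itertools.product(*per_unit_choices):
        mass = sum(a.mass + b.mass for a, b in choice)
        key = tuple((a.met_lost, b.met_lost) for a, b in choice)
        variants.append(TheoreticalComplex(comp, key, mass))
    variants.sort(key=lambda v: (v.neutral_mass, v.variant_key))
    deduped: list[TheoreticalComplex] = []
    for v in variants:
        if deduped and abs(v.neutral_mass - deduped[-1].neutral_mass) < MASS_DEDUP_TOL:
            continue
        deduped.append(v)
    return deduped


def decoy_compositions(
    strains: Sequence[str],
    registry: ProteoformRegistry,
    n_dimers_hexamer: int = 3,
) -> list[ComplexComposition]:
    """Negative-control compositions: cross-family hexamers, cross-strain dimers.

    Cross-family hexamers mix APC and PC dimer units (within whatever
    strains carry both families); cross-strain dimers pair the α of one
    strain with the β of another.  Both classes are flagged ``is_decoy``
    and travel the same matching path as genuine candidates.
    """
    out: list[ComplexComposition] = []
    # cross-family hexamers over all (strain, family) pure units
    units = sorted(
        DimerUnit(f, s)
        for s in set(strains)
        for f in registry.families_of(s)
    )
    seen = set()
    for combo in itertools.combinations_with_replacement(units, n_dimers_hexamer):
        if len({u.family for u in combo}) > 1 and combo not in seen:
            seen.add(combo)
            out.append(ComplexComposition(combo, is_decoy=True))
    # cross-strain αβ decoy dimers, per family
    for family in Family:
        have = [s for s in strains
                if registry.has(s, family, Chain.ALPHA)
                and registry.has(s, family, Chain.BETA)]
        for a, b in itertools.permutations(have, 2):
            out.append(
                ComplexComposition(
                    (DimerUnit(family, a, beta_strain_id=b),), is_decoy=True
                )
            )
    return out


def candidate_table(complexes: Iterable[TheoreticalComplex]) -> pd.DataFrame:
    """Tabulate theoretical complexes for inspection or CSV export."""
    rows = []
    for tc in complexes:
        comp = tc.composition
        rows.append({
            "label": comp.label,
            "family": "/".join(sorted(f.value for f in comp.families)),
            "n_dimers": comp.n_dimers,
            "is_decoy": comp.is_decoy,
            "n_met_lost": tc.n_met_lost,
            "neutral_mass_da": tc.neutral_mass,
        })
    return pd.DataFrame(rows).sort_values(
        ["family", "n_dimers", "neutral_mass_da"], ignore_index=True
    ) if rows else pd.DataFrame(
        columns=["label", "family", "n_dimers", "is_decoy",
                 "n_met_lost", "neutral_mass_da"]
    )


def write_candidates_csv(complexes: Iterable[TheoreticalComplex],
                         path: Union[str, Path]) -> None:
    candidate_table(complexes).to_csv(path, index=False)


def expand_candidates(
    compositions: Iterable[ComplexComposition],
    registry: ProteoformRegistry,
) -> list[TheoreticalComplex]:
    """Mass-expand many compositions at once (ordering: composition, mass)."""
    out: list[TheoreticalComplex] = []
    for comp in compositions:
        out.extend(composition_mass_variants(comp, registry))
    return out
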