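"""Reproducible pipeline stages: simulate, candidates, assign, conserve, contacts.

Every stage is a pure function of a :class:`PipelineConfig` (a JSON file
plus overrides).  The seed is mandatory and is recorded, together with a
hash of the canonical config, in every report so that two runs with the
same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Union

import numpy as np
import pandas as pd

from . import __version__
from .proteoform import (
    Chain, DEFAULT_CONSTANTS, Family, MassConstants,
    read_subunit_fasta, write_subunit_fasta,
)
from .complexes import (
    ProteoformRegistry, decoy_compositions, enumerate_compositions,
    expand_candidates, candidate_table, write_candidates_csv,
)
from .simulate import (
    InstrumentModel, MixtureSpec, generate_strain_family,
    read_spectrum_csv, render_spectrum, write_spectrum_csv,
)
from .assign import AssignmentResults, SpectrumAssigner
from .conservation import (
    DEFAULT_SIMILARITY_CLASSES, MultipleAlignment, column_stats,
    interface_conservation_summary,
)
from . import interface as _interface

log = logging.getLogger("phycomatch")

__all__ = ["PipelineConfig", "RunReport", "run_simulate", "run_candidates",
           "run_assign", "run_conserve", "run_contacts"]


@dataclass(frozen=True)
class PipelineConfig:
    """Validated pipeline configuration.

    ``raw`` keeps the canonical JSON-serializable dict used for hashing.
    Unknown top-level keys are rejected so typos fail loudly.
    """

    seed: int
    out_dir: Path
    constants: MassConstants
    instrument: InstrumentModel
    simulate: dict[str, Any]
    assignment: dict[str, Any]
    paths: dict[str, str]
    similarity_classes: tuple[frozenset[str], ...]
    chain_grouping: dict[str, int]
    chain_to_row: dict[str, str]
    contact_cutoff: float
    raw: dict[str, Any] = field(compare=False)

    _KNOWN = {"seed", "out_dir", "mass_constants", "instrument", "simulate",
              "assignment", "paths", "similarity_classes", "chain_grouping",
              "chain_to_row", "contact_cutoff"}

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        unknown = set(data) - cls._KNOWN
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in data:
            raise ValueError("config must set an integer 'seed' (reproducibility)")
        seed = int(data["seed"])
        constants = MassConstants(**data.get("mass_constants", {})) \
            if "mass_constants" in data else DEFAULT_CONSTANTS
        inst_kwargs = dict(data.get("instrument", {}))
        inst_kwargs.setdefault("seed", seed)
        instrument = InstrumentModel(**inst_kwargs)
        classes = tuple(
            frozenset(c) for c in data.get(
                "similarity_classes",
                ["".join(sorted(c)) for c in DEFAULT_SIMILARITY_CLASSES],
            )
        )
        return cls(
            seed=seed,
            out_dir=Path(data.get("out_dir", "phycomatch_out")),
            constants=constants,
            instrument=instrument,
            simulate=dict(data.get("simulate", {})),
            assignment=dict(data.get("assignment", {})),
            paths=dict(data.get("paths", {})),
            similarity_classes=classes,
            chain_grouping={k: int(v) for k, v in data.get("chain_grouping", {}).items()},
            chain_to_row=dict(data.get("chain_to_row", {})),
            contact_cutoff=float(data.get("contact_cutoff", 3.0)),
            raw=json.loads(json.dumps(data, sort_keys=True)),
        )

    @classmethod
    def from_json(cls, path: Union[str, Path], **overrides: Any) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(data)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True).encode()
        ).hexdigest()[:16]

    def provenance(self) -> dict[str, Any]:
        return {"config_hash": self.hash(), "seed": self.seed,
                "phycomatch_version": __version__}


@dataclass
class RunReport:
    """Per-stage outputs: a JSON-able summary plus named tables."""

    stage: str
    summary: dict[str, Any]
    tables: dict[str, pd.DataFrame]
    provenance: dict[str, Any]

    def write(self, out_dir: Union[str, Path]) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        report = {"stage": self.stage, "summary": self.summary,
                  "provenance": self.provenance}
        p = out_dir / f"{self.stage}_report.json"
        p.write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
        paths["report"] = p
        for name, df in self.tables.items():
            tp = out_dir / f"{self.stage}_{name}.csv"
            df.to_csv(tp, index=False)
            paths[name] = tp
        return paths


def _demo_families(config: PipelineConfig):
    """Generate the configured synthetic strain families."""
    sim = config.simulate
    fams = [Family(f) for f in sim.get("families", ["APC", "PC"])]
    out = {}
    for i, fam in enumerate(fams):
        out[fam] = generate_strain_family(
            family=fam,
            n_strains=int(sim.get("n_strains", 2)),
            divergence=float(sim.get("divergence", 0.05)),
            seed=config.seed * 10 + i,
            constants=config.constants,
            min_relative_gap=sim.get("min_relative_gap", 0.001),
        )
    return out


def _load_registry(config: PipelineConfig) -> ProteoformRegistry:
    seq_path = config.paths.get("sequences")
    if seq_path is None:
        raise ValueError("config paths.sequences is required for this stage")
    seqs = read_subunit_fasta(seq_path)
    return ProteoformRegistry.from_sequences(seqs, config.constants)


def _all_candidates(registry: ProteoformRegistry, include_decoys: bool = True):
    comps = []
    for fam in Family:
        strains = registry.strains(fam)
        if not strains:
            continue
        comps += enumerate_compositions(strains, fam, 1, registry=registry)
        comps += enumerate_compositions(strains, fam, 3, registry=registry)
    if include_decoys:
        strains = sorted({s for fam in Family for s in registry.strains(fam)})
        comps += decoy_compositions(strains, registry)
    return expand_candidates(comps, registry)


def run_simulate(config: PipelineConfig) -> RunReport:
    """Generate strain sequences and a mixed spectrum with known truth."""
    log.info("simulate: generating strain families (seed=%d)", config.seed)
    out_dir = config.out_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    families = _demo_families(config)
    rng = np.random.default_rng(config.seed)

    all_seqs = [s for fs in families.values() for s in fs.sequences]
    registry = ProteoformRegistry.from_sequences(all_seqs, config.constants)
    write_subunit_fasta(all_seqs, out_dir / "sequences.fasta")

    sim = config.simulate
    dimer_weight = float(sim.get("dimer_weight", 0.0))
    truth_rows = []
    spectrum_paths: dict[str, str] = {}
    n_species = 0
    # one spectrum per family: APC and PC envelopes would otherwise overlay
    # in m/z, as when measuring separately purified complexes
    for fam, fs in families.items():
        strains = sorted({s.strain_id for s in fs.sequences})
        members = []
        hexamers = enumerate_compositions(strains, fam, 3, registry=registry)
        weights = rng.uniform(size=len(hexamers))
        weights /= weights.sum()
        for comp, w in zip(hexamers, weights):
            variants = expand_candidates([comp], registry)
            for tc in variants:
                members.append((tc, (1.0 - dimer_weight) * w / len(variants)))
        if dimer_weight > 0:
            dimers = enumerate_compositions(strains, fam, 1, registry=registry)
            dw = rng.uniform(size=len(dimers))
            dw /= dw.sum()
            for comp, w in zip(dimers, dw):
                variants = expand_candidates([comp], registry)
                for tc in variants:
                    members.append((tc, dimer_weight * w / len(variants)))
        mixture = MixtureSpec(tuple(members))
        spectrum = render_spectrum(mixture, config.instrument)
        path = out_dir / f"spectrum_{fam.value}.csv"
        write_spectrum_csv(spectrum, path)
        spectrum_paths[fam.value] = str(path)
        n_species += len(members)
        truth_rows += [
            {"family": fam.value, "label": tc.composition.label,
             "variant": tc.label, "neutral_mass_da": tc.neutral_mass,
             "weight": w}
            for tc, w in mixture.normalized
        ]
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(out_dir / "truth.csv", index=False)
    log.info("simulate: %d species rendered over %d spectra",
             n_species, len(spectrum_paths))
    return RunReport(
        stage="simulate",
        summary={
            "n_species": n_species,
            "spectra": spectrum_paths,
            "sequences": str(out_dir / "sequences.fasta"),
            "truth": str(out_dir / "truth.csv"),
        },
        tables={"truth": truth},
        provenance=config.provenance(),
    )


def run_candidates(config: PipelineConfig) -> RunReport:
    """Enumerate the candidate (and decoy) theoretical complex table."""
    registry = _load_registry(config)
    cands = _all_candidates(registry)
    table = candidate_table(cands)
    log.info("candidates: %d theoretical masses", len(table))
    return RunReport(
        stage="candidates",
        summary={"n_candidates": len(table),
                 "n_decoys": int(table.is_decoy.sum())},
        tables={"table": table},
        provenance=config.provenance(),
    )


def run_assign(config: PipelineConfig) -> RunReport:
    """Deconvolve + match a spectrum against the candidate table."""
    registry = _load_registry(config)
    spec_path = config.paths.get("spectrum")
    if spec_path is None:
        raise ValueError("config paths.spectrum is required for assignment")
    spectrum = read_spectrum_csv(spec_path)
    cands = _all_candidates(registry)
    model = SpectrumAssigner(spectrum, cands, **config.assignment)
    res = model.fit()
    for a in res.assignments:
        for tc, err in a.candidates:
            log.debug("match M=%.1f -> %s (%.4f%%, %.1f ppm)",
                      a.series.neutral_mass, tc.label, err, err * 1e4)
    log.info("assign: %d series, %d assigned", len(res.series),
             sum(1 for a in res.assignments if a.candidates))
    ab = res.abundance
    return RunReport(
        stage="assign",
        summary={
            "n_centroids": len(res.centroids),
            "n_series": len(res.series),
            "dimer_to_hexamer_pct": ab.dimer_to_hexamer_pct,
            "decoy_intensity_pct": ab.decoy_intensity_pct,
            "text_summary": res.summary(),
        },
        tables={
            "assignments": res.assignment_table(),
            "abundance": ab.composition_table,
        },
        provenance=config.provenance(),
    )


def run_conserve(config: PipelineConfig) -> RunReport:
    """Interface conservation: structure contacts → alignment columns → stats."""
    aln_path = config.paths.get("alignment")
    if aln_path is None:
        raise ValueError("config paths.alignment is required for conservation")
    alignment = MultipleAlignment.from_fasta(aln_path)
    struct_path = config.paths.get("structure")
    if struct_path:
        if not config.chain_to_row:
            raise ValueError(
                "config chain_to_row (structure chain -> alignment row) is "
                "required when a structure is given"
            )
        structure = _interface.read_structure(struct_path)
        cols_by_chain = _interface.derive_interface_columns(
            structure, config.chain_grouping, alignment,
            config.chain_to_row, config.contact_cutoff,
        )
        columns = sorted({c for cols in cols_by_chain.values() for c in cols})
    else:
        columns = [int(c) for c in config.paths.get("interface_columns", "").split(",")
                   if c.strip()] or None
        if not columns:
            raise ValueError(
                "give either paths.structure (+chain_to_row) or a "
                "paths.interface_columns comma list"
            )
    summary = interface_conservation_summary(
        alignment, columns, config.similarity_classes
    )
    stats = column_stats(alignment, config.similarity_classes)
    log.info("conserve: %d interface columns, identity %.1f%%, similarity %.1f%%",
             summary.n_columns, summary.mean_identity_pct,
             summary.mean_similarity_pct)
    return RunReport(
        stage="conserve",
        summary={
            "interface_columns": list(columns),
            "mean_identity_pct": summary.mean_identity_pct,
            "mean_similarity_pct": summary.mean_similarity_pct,
            "n_columns": summary.n_columns,
            "skipped_columns": list(summary.skipped_columns),
        },
        tables={"column_stats": stats},
        provenance=config.provenance(),
    )


def run_contacts(config: PipelineConfig) -> RunReport:
    """Cross-dimer contacts and (optional) PAE/pLDDT interface confidence."""
    struct_path = config.paths.get("structure")
    if struct_path is None:
        raise ValueError("config paths.structure is required for contacts")
    structure = _interface.read_structure(struct_path)
    contacts = _interface.find_contacts(
        structure, config.chain_grouping, config.contact_cutoff
    )
    table = pd.DataFrame([dataclasses.asdict(c) for c in contacts])
    summary: dict[str, Any] = {"n_contacts": len(contacts),
                               "cutoff_angstrom": config.contact_cutoff}
    if config.paths.get("pae") and contacts:
        pae = _interface.read_pae_json(config.paths["pae"])
        plddt = _interface.plddt_from_structure(structure)
        idx = _interface.residue_index(structure)
        conf = _interface.summarize_confidence(
            pae, plddt,
            _interface.interface_residues(contacts, config.chain_grouping),
            idx, n_contacts=len(contacts),
        )
        summary.update({
            "mean_interface_pae": conf.mean_interface_pae,
            "mean_interface_plddt": conf.mean_interface_plddt,
            "n_interface_residues": conf.n_interface_residues,
        })
    log.info("contacts: %d pairs within %.1f A", len(contacts),
             config.contact_cutoff)
    return RunReport(stage="contacts", summary=summary,
                     tables={"contacts": table},
                     provenance=config.provenance())
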