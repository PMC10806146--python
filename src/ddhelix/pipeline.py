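"""End-to-end orchestration: simulate/load -> build -> debump -> analyze -> scan.

A single :class:`RunConfig` drives the whole chain and is echoed, together
with the seed and content hashes of every product, into a manifest so a run
can be reproduced exactly.  All outputs are computed in memory first and
written at the end, so a failing stage leaves no partial bundle behind.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .assembly import LayerPlan, build_extended_layer, reanchor, thread_query
from .clashes import relieve
from .interfaces import (DEFAULT_CONTACT_CUTOFF, PotentialParams,
                         SYNTHETIC_FACES, classify_interface, contact_map,
                         face_offsets, per_residue_energy, rank_residues)
from .mutations import MutationSpec, delta_score, apply_mutation, synthetic_panel
from .structure import chain_sequence, read_pdb, write_pdb
from .synthetic import LatticeSpec, make_lattice

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    template_pdb: str | None = None  # None -> synthetic fixture
    lattice: dict = field(default_factory=dict)  # LatticeSpec overrides
    query_pdb: str | None = None
    query_sequence: str | None = None  # threaded if no query_pdb
    thread_on_chain: str | None = None  # template chain for threading
    target_chains: list[str] | None = None
    anchor_chains: list[str] | None = None
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF
    energy_cutoff: float = 10.0
    overlap_threshold: float = 0.4
    debump_max_iters: int = 150
    run_scan: bool = True
    mutations: list[str] | None = None  # e.g. ["K2E"]; None -> marker panel
    seed: int = 0
    outdir: str = "ddhelix_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def potential(self) -> PotentialParams:
        return PotentialParams(cutoff=self.energy_cutoff)


def _parse_mutation(text: str) -> MutationSpec:
    return MutationSpec(position=int(text[1:-1]), from_aa=text[0].upper(),
                        to_aa=text[-1].upper())


def _sha256(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full chain and write the output bundle to ``config.outdir``.

    Products: ``assembly.pdb``, ``contacts.tsv``, ``energies.tsv``,
    ``offsets.json``, ``scan.tsv`` (optional), ``debump.json`` and
    ``manifest.json``.  Returns the manifest.
    """
    stage = "template"
    try:
        if config.template_pdb is not None:
            path = Path(config.template_pdb)
            if not path.exists():
                raise FileNotFoundError(f"template PDB not found: {path}")
            template = read_pdb(path)
            manifest_lattice = None
        else:
            spec = LatticeSpec(seed=config.seed, **config.lattice)
            template, manifest_lattice = make_lattice(spec)

        stage = "plan"
        if manifest_lattice is not None and config.target_chains is None:
            plan = LayerPlan.from_manifest(manifest_lattice)
            anchors = config.anchor_chains or \
                plan.layer_chain_ids["IRAK2"]
        else:
            if not config.target_chains or not config.anchor_chains:
                raise ValueError("target_chains and anchor_chains are "
                                 "required with an external template")
            layer_ids = {"MYD88": [], "IRAK4": config.target_chains[:4],
                         "IRAK2": config.target_chains[4:]}
            known = [c.id for c in template.chains]
            layer_ids["MYD88"] = [c for c in known
                                  if c not in config.target_chains]
            plan = LayerPlan(layer_chain_ids=layer_ids,
                             targets=list(config.target_chains))
            anchors = list(config.anchor_chains)

        stage = "query"
        if config.query_pdb:
            query = read_pdb(config.query_pdb)
        else:
            chain_id = config.thread_on_chain or plan.targets[0]
            tchain = template.chain(chain_id)
            seq = config.query_sequence or chain_sequence(tchain)
            query = thread_query(tchain, seq)

        stage = "build"
        asm = build_extended_layer(query, template, plan)
        asm = reanchor(asm, template, anchors)

        stage = "debump"
        asm, debump_report = relieve(
            asm, max_iters=config.debump_max_iters, seed=config.seed,
            overlap_threshold=config.overlap_threshold)

        stage = "analyze"
        params = config.potential()
        contacts = contact_map(asm, cutoff=config.contact_cutoff)
        contacts_df = pd.DataFrame([{
            "subunit_i": c.subunit_i, "res_i": c.residue_i,
            "subunit_j": c.subunit_j, "res_j": c.residue_j,
            "dist": round(c.distance, 3), "offset": c.offset,
            "type": classify_interface(c.offset),
        } for c in contacts])
        energies = rank_residues(per_residue_energy(asm, params))
        energies_df = pd.DataFrame([{
            "residue": e.residue, "resname": e.resname,
            "aggregated": round(e.aggregated, 4),
            "n_copies": len(e.per_copy), "flagged": e.flagged,
        } for e in energies])
        offsets = {}
        for face_name, face in SYNTHETIC_FACES.items():
            try:
                offsets[face_name] = {
                    str(p): {"nearest": v["nearest"], "histogram": v["histogram"]}
                    for p, v in face_offsets(asm, contacts, face).items()}
            except KeyError:
                offsets[face_name] = "pivot absent from query model"

        stage = "scan"
        scan_rows = []
        if config.run_scan:
            panel = ([_parse_mutation(m) for m in config.mutations]
                     if config.mutations else synthetic_panel())
            for m in panel:
                mut = apply_mutation(asm, m, seed=config.seed)
                ds = delta_score(asm, mut, m, params)
                for dn, de in ds["by_offset"].items():
                    scan_rows.append({"mutation": m.label, "offset": dn,
                                      "class": classify_interface(dn),
                                      "delta_energy": round(de, 4)})
        scan_df = pd.DataFrame(scan_rows)

        stage = "write"
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        structure = asm.to_structure(title="extended DD assembly")
        write_pdb(structure, outdir / "assembly.pdb")
        contacts_df.to_csv(outdir / "contacts.tsv", sep="\t", index=False)
        energies_df.to_csv(outdir / "energies.tsv", sep="\t", index=False)
        (outdir / "offsets.json").write_text(json.dumps(offsets, indent=1))
        if config.run_scan:
            scan_df.to_csv(outdir / "scan.tsv", sep="\t", index=False)
        (outdir / "debump.json").write_text(json.dumps(debump_report, indent=1))
        hashes = {p.name: _sha256(p.read_bytes())
                  for p in sorted(outdir.iterdir()) if p.name != "manifest.json"}
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config": asdict(config),
            "lattice_ground_truth": manifest_lattice,
            "assembly": asm.manifest(),
            "n_contacts": len(contacts),
            "debump": {k: debump_report[k] for k in
                       ("initial_clashes", "final_clashes", "iterations",
                        "converged")},
            "output_hashes": hashes,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return manifest
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
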