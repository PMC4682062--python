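"""Orchestration of the dock -> minimize -> re-dock (D1-EM-D2) workflow.

Starting from a linear epitope sequence and a supported allotype, the
pipeline threads the sequence onto the allotype's epitope-pattern backbone,
relaxes the lone peptide, runs a first docking stage (D1) inside the cleft
grid box, screens every pose's position and orientation, picks the consensus
best pose, assembles and energy-minimizes the peptide:MHC complex, then
refines with a second docking stage (D2) run and scored exactly like D1.
Any stage failure aborts the run with a stage-labelled report rather than an
exception, mirroring a stop-on-error batch workflow.

Both docking stages share one code path (:func:`_docking_stage`); D1 and D2
draw independent RNG streams derived from the master seed, so the whole run
is bit-reproducible with the built-in mock backends.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np

from . import epitope_builder
from .backends import (DockingJobSpec, EMConfig, MockDockingBackend,
                       MockEMBackend)
from .cleft import (CleftCheckParams, CleftCheckReport, compute_grid_box,
                    check_pose_in_cleft)
from .consensus import ConsensusResult, PoseEnsemble, run_consensus
from .errors import BackendError, PipelineError, PmhcdockError
from .registry import AllotypeRegistry, TemplateEntry
from .structure_io import (Structure, assign_chain_roles, sanitize_structure,
                           write_pdb)

PEPTIDE_CHAIN_ID = "P"


@dataclasses.dataclass
class PipelineConfig:
    registry: AllotypeRegistry
    docking_backend: object = dataclasses.field(default_factory=MockDockingBackend)
    em_backend: object = dataclasses.field(default_factory=MockEMBackend)
    em_config: EMConfig = dataclasses.field(default_factory=EMConfig)
    cleft_params: CleftCheckParams = dataclasses.field(default_factory=CleftCheckParams)
    n_runs: int = 20
    box_padding: float = 8.0


@dataclasses.dataclass
class PipelineResult:
    status: str  # "finalized" | "aborted"
    final_complex: Structure | None = None
    d1_consensus: ConsensusResult | None = None
    d2_consensus: ConsensusResult | None = None
    cleft_reports: dict = dataclasses.field(default_factory=dict)
    stage_log: list = dataclasses.field(default_factory=list)

    def stage_report(self) -> dict:
        return {
            "status": self.status,
            "stages": [
                {"stage": s, "status": st, **meta}
                for s, st, meta in self.stage_log
            ],
            "cleft_reports": {k: v.to_dict() if isinstance(v, CleftCheckReport)
                              else v for k, v in self.cleft_reports.items()},
        }

    def stage_report_json(self, **kwargs) -> str:
        return json.dumps(self.stage_report(), **kwargs)


def derive_seed(master_seed: int, stage_index: int) -> int:
    """Independent per-stage seed stream, kept below 2**31."""
    ss = np.random.SeedSequence([abs(int(master_seed)), stage_index])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def dock(spec: DockingJobSpec, backend, seed: int) -> PoseEnsemble:
    """Run the docking backend and validate its contract."""
    if not spec.box.contains(spec.peptide.coords_array()).any():
        raise PipelineError("search box does not contain the peptide start position")
    ensemble = backend.dock(spec, seed)
    if len(ensemble) != spec.n_runs:
        raise PipelineError(
            f"backend returned {len(ensemble)} poses for {spec.n_runs} runs")
    return ensemble


def minimize(complex_structure: Structure, config: EMConfig, backend) -> Structure:
    """Energy-minimize a peptide:MHC complex (all residues flexible)."""
    try:
        return backend.minimize(complex_structure, config=config, mobile="all")
    except BackendError as exc:
        raise BackendError(f"complex minimization failed: {exc}",
                           stage="energy minimization") from exc


def assemble_complex(receptor: Structure, peptide: Structure,
                     peptide_chain_id: str = PEPTIDE_CHAIN_ID) -> Structure:
    """Receptor chains (MHC heavy chain, beta2m) plus the peptide chain."""
    used = set(a.chain_id for a in receptor.atoms)
    cid = peptide_chain_id
    if cid in used:
        for candidate in "PQZYXWVUTSR":
            if candidate not in used:
                cid = candidate
                break
    atoms = [a.copy() for a in receptor.atoms]
    for a in peptide.atoms:
        b = a.copy()
        b.chain_id = cid
        atoms.append(b)
    for serial, atom in enumerate(atoms, start=1):
        atom.serial = serial
    return Structure(atoms)


def _receptor_only(complex_structure: Structure) -> tuple[Structure, Structure]:
    """Split a pMHC complex into (receptor chains, peptide chain)."""
    roles = assign_chain_roles(complex_structure)
    receptor_ids = [c for c in complex_structure.chains() if c != roles.peptide]
    return (complex_structure.subset(receptor_ids),
            complex_structure.subset([roles.peptide]))


def _docking_stage(label: str, receptor: Structure, peptide: Structure,
                   template: TemplateEntry, config: PipelineConfig,
                   seed: int, log: list, cleft_reports: dict):
    """One docking round: dock, screen every pose in the cleft, consensus.

    Shared verbatim by D1 and D2. Returns (ensemble, consensus, selected
    pose structure) or raises PipelineError with a stage-labelled message.
    """
    box = compute_grid_box(template, config.box_padding)
    spec = DockingJobSpec(receptor=receptor, peptide=peptide, box=box,
                          n_runs=config.n_runs)
    ensemble = dock(spec, config.docking_backend, seed)
    kept = []
    reports = []
    for pose in ensemble.poses:
        report = check_pose_in_cleft(pose.coords, template, box,
                                     config.cleft_params)
        reports.append(report)
        if report.passed:
            kept.append(pose)
    cleft_reports[label] = [r.to_dict() for r in reports]
    log.append((f"{label} cleft screen", "ok",
                {"poses": len(ensemble), "passed": len(kept)}))
    if not kept:
        raise PipelineError(
            f"{label}: all {len(ensemble)} poses failed the cleft check")
    screened = PoseEnsemble(kept)
    result = run_consensus(screened)
    selected = screened.poses[result.selected_index]
    cleft_reports[f"{label}_selected"] = check_pose_in_cleft(
        selected.coords, template, box, config.cleft_params)
    return screened, result, selected.coords.copy()


def model_pmhc(sequence: str, allotype: str, config: PipelineConfig,
               seed: int = 0, out_path: str | Path | None = None
               ) -> PipelineResult:
    """Model a peptide:MHC-I complex from the epitope's linear sequence.

    Executes thread -> relax -> D1 dock -> cleft screen -> consensus ->
    assemble -> EM -> D2 dock -> cleft screen -> consensus, returning the
    final complex. On any stage error the result carries status ``aborted``
    and the stage log records where and why.
    """
    result = PipelineResult(status="aborted")
    log = result.stage_log

    def stage(label):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                value = fn()
            except (PmhcdockError, BackendError) as exc:
                log.append((label, "error", {"reason": str(exc)}))
                raise _Abort from exc
            log.append((label, "ok",
                        {"seconds": round(time.perf_counter() - t0, 4)}))
            return value
        return wrap

    try:
        seq = sequence.strip().upper()

        def validate():
            compatible = epitope_builder.validate_sequence(seq, config.registry)
            entry = config.registry.get(allotype, len(seq))
            if entry not in compatible:
                raise PipelineError(
                    f"allotype {allotype} does not accept {len(seq)}-mers")
            if not entry.has_structures:
                raise PipelineError(
                    f"template {allotype}/{len(seq)} has no structures "
                    f"attached (registry config needed)")
            return entry
        template = stage("validation")(validate)

        peptide = stage("epitope threading")(
            lambda: epitope_builder.thread_peptide(seq, template,
                                                   chain_id=PEPTIDE_CHAIN_ID))
        peptide = stage("epitope relaxation")(
            lambda: epitope_builder.relax_epitope(
                peptide, config.em_backend, config.em_config))

        receptor = sanitize_structure(template.mhc_donor)
        if any(r.is_protein and 8 <= len(residues) <= 12
               for residues in receptor.chains().values()
               for r in residues[:1]):
            # donor still carries its own peptide: drop it before docking
            receptor, _ = _receptor_only(receptor)

        def d1():
            return _docking_stage("D1", receptor, peptide, template, config,
                                  derive_seed(seed, 1), log,
                                  result.cleft_reports)
        _, result.d1_consensus, d1_pose = stage("D1 docking + consensus")(d1)

        complex_d1 = stage("complex assembly")(
            lambda: assemble_complex(receptor, d1_pose))
        minimized = stage("energy minimization")(
            lambda: minimize(complex_d1, config.em_config, config.em_backend))

        em_receptor, em_peptide = _receptor_only(minimized)

        def d2():
            return _docking_stage("D2", em_receptor, em_peptide, template,
                                  config, derive_seed(seed, 2), log,
                                  result.cleft_reports)
        _, result.d2_consensus, d2_pose = stage("D2 docking + consensus")(d2)

        final = stage("final assembly")(
            lambda: assemble_complex(em_receptor, d2_pose))
        result.final_complex = final
        result.status = "finalized"
        if out_path is not None:
            write_pdb(final, out_path)
            log.append(("output", "ok", {"path": str(out_path)}))
    except _Abort:
        result.status = "aborted"
    return result


class _Abort(Exception):
    """Internal control flow: stage recorded its error, stop the pipeline."""
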