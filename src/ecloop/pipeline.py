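"""End-to-end loop-modeling pipeline.

Stages run in order: prepare -> sample -> reconstruct -> score -> cluster
-> select -> evaluate.  Every stage appends to the run directory (earlier
outputs are never rewritten), all random streams derive from the single
config seed, and re-running an identical config reproduces identical
reports.

The configuration is one declarative mapping (YAML on disk); see
``PipelineConfig`` for keys and defaults.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from . import cg_model, fixtures, reconstruct, sampler, secstruct, select_eval
from .forcefield import ForceFieldParams
from .sampler import LoopSystem, MCConfig, Trajectory
from .structure_io import (LoopDefinition, ReceptorStructure,
                           read_loop_definitions, read_structure,
                           select_loop_boundaries, write_loop_definitions,
                           write_structure)


@dataclasses.dataclass
class PipelineConfig:
    outdir: str = "ecloop_run"
    structure: str | None = None      # scaffold PDB (None -> toy receptor)
    loops: str | None = None          # loop-definition TSV (None -> derive)
    ss: str | None = None             # SS file, loop_id<TAB>HEC string
    reference: str | None = None      # reference PDB (default: the scaffold)
    toy: dict = dataclasses.field(default_factory=dict)  # make_toy_receptor kwargs
    mc: dict = dataclasses.field(default_factory=dict)   # MCConfig overrides
    forcefield: dict = dataclasses.field(default_factory=dict)
    K: int = 100
    refine_steps: int = 5
    atom_mode: str = "CA"
    primary_loop: str | None = None   # loop_id to evaluate (default: longest)
    write_models: bool = True
    max_model_files: int = 500
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclasses.dataclass
class PreparedSystem:
    structure: ReceptorStructure
    reference: ReceptorStructure
    loops: list[LoopDefinition]
    primary: LoopDefinition
    system: LoopSystem
    ss: str                            # one label per mobile residue
    params: ForceFieldParams


def prepare(config: PipelineConfig) -> PreparedSystem:
    """Load (or synthesize) the receptor and assemble the CG system."""
    if config.structure is None:
        toy = fixtures.make_toy_receptor(seed=config.seed, **config.toy)
        structure = toy.structure
        loops = [toy.loop]
    else:
        structure = read_structure(config.structure)
        if config.loops:
            loops = read_loop_definitions(config.loops)
        else:
            loops = select_loop_boundaries(structure)
    reference = (read_structure(config.reference) if config.reference
                 else structure)

    if config.primary_loop:
        primary = next(l for l in loops if l.loop_id == config.primary_loop)
    else:
        primary = max(loops, key=lambda l: len(l.sequence))

    chain = cg_model.allatom_to_cg(structure, loops)
    bonds = []
    for b in structure.declared_disulfides:
        bonds.append((structure.chain.index_of(b.residue_a, b.icode_a),
                      structure.chain.index_of(b.residue_b, b.icode_b)))

    params = ForceFieldParams(**config.forcefield)
    if bonds:
        params = params.declare_disulfides()

    ss_by_loop = secstruct.read_ss_file(config.ss) if config.ss else {}
    labels = []
    for loop in sorted(loops, key=lambda l: l.first):
        ss = ss_by_loop.get(loop.loop_id, "C" * len(loop.sequence))
        secstruct.validate_ss(ss, loop)
        labels.append(ss)
    ss = "".join(labels)

    system = LoopSystem(chain=chain, scaffold_ref=chain.ca.copy(),
                        bonds=bonds, ss=ss)
    return PreparedSystem(structure, reference, loops, primary, system, ss,
                          params)


def _loop_segments(system: LoopSystem) -> list[tuple[int, int]]:
    mask = system.chain.anchor_mask
    segs, i, n = [], 0, len(mask)
    while i < n:
        if not mask[i]:
            j = i
            while j < n and not mask[j]:
                j += 1
            segs.append((i, j - 1))
            i = j
        else:
            i += 1
    return segs


def reconstruct_model(prep: PreparedSystem, snapshot: np.ndarray,
                      mobile_indices: np.ndarray,
                      refine_steps: int = 5) -> ReceptorStructure:
    """All-atom model from one snapshot: backbone, side chains, insertion,
    short refinement -- per mobile loop segment."""
    chain = prep.system.chain
    ca = chain.ca.copy()
    ca[mobile_indices] = snapshot
    model = prep.structure
    residues = prep.structure.chain.residues
    for (i0, i1) in _loop_segments(prep.system):
        # include one flanking anchor on each side for proper junction frames
        lo, hi = max(i0 - 1, 0), min(i1 + 1, len(ca) - 1)
        names = [chain.names[i] for i in range(lo, hi + 1)]
        backbone = reconstruct.ca_to_backbone(ca[lo:hi + 1], names)
        allatom = reconstruct.place_side_chains(backbone)
        loop_model = allatom[i0 - lo:i0 - lo + (i1 - i0 + 1)]
        loopdef = LoopDefinition(
            f"seg{i0}", residues[i0].number, residues[i1].number,
            _segment_sequence(chain, i0, i1),
        )
        model = reconstruct.insert_loop(model, loop_model, loopdef)
        if refine_steps > 0:
            model = reconstruct.refine(model, refine_steps, loopdef)
    return model


def _segment_sequence(chain, i0: int, i1: int) -> str:
    from .structure_io import THREE_TO_ONE
    return "".join(THREE_TO_ONE.get(chain.names[i], "X")
                   for i in range(i0, i1 + 1))


def run_pipeline(config: PipelineConfig | str | Path) -> Path:
    """Execute all stages; returns the run directory.

    Writes: the prepared scaffold and loop definitions, the CA trajectory
    with its energy sidecar, the per-model manifest, optional numbered
    model PDBs, and the selection report (JSON + TSV).
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"seed: {config.seed}"]

    prep = prepare(config)
    write_structure(prep.structure, outdir / "scaffold.pdb")
    write_loop_definitions(prep.loops, outdir / "loops.tsv")

    mc = MCConfig(seed=config.seed, **config.mc)
    log_lines.append(f"mc_config_hash: {mc.hash()}")
    trajectories = sampler.run_sampling(prep.system, prep.ss, prep.params, mc)
    sampler.write_trajectory(trajectories, prep.system,
                             outdir / "trajectory_ca.pdb",
                             outdir / "trajectory_energies.tsv")

    # flatten the ensemble
    snapshots: list[np.ndarray] = []
    run_ids: list[int] = []
    for traj in trajectories:
        snapshots.extend(traj.snapshots)
        run_ids.extend([traj.run_id] * len(traj.snapshots))
    mobile = trajectories[0].mobile_indices
    n_models = len(snapshots)
    log_lines.append(f"ensemble_size: {n_models}")

    # reconstruct + score
    models: list[ReceptorStructure] = []
    scores = []
    write_n = config.max_model_files if config.write_models else 0
    models_dir = outdir / "models"
    if write_n:
        models_dir.mkdir(exist_ok=True)
    for m, snap in enumerate(snapshots):
        model = reconstruct_model(prep, snap, mobile, config.refine_steps)
        models.append(model)
        scores.append(select_eval.single_point_energy(model, model_id=m))
        if m < write_n:
            write_structure(model, models_dir / f"model_{m + 1:04d}.pdb")

    # cluster on primary-loop CA coordinates (common scaffold frame)
    chain = prep.structure.chain
    p0 = chain.index_of(prep.primary.first)
    p1 = chain.index_of(prep.primary.last)
    sel = np.isin(mobile, np.arange(p0, p1 + 1))
    loop_ca = np.array([snap[sel] for snap in snapshots])
    K = min(config.K, n_models)
    clusters = select_eval.cluster_models(loop_ca, K=K, seed=config.seed)

    # evaluate against the reference
    rmsds = {}
    for m, model in enumerate(models):
        sup = select_eval.superpose_excluding_loop(model, prep.reference,
                                                   prep.loops)
        rmsds[m] = select_eval.loop_rmsd(model, prep.reference, prep.primary,
                                         atom_mode=config.atom_mode,
                                         transform=sup)
    report = select_eval.select_models(scores, clusters, rmsds)

    manifest = outdir / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("model_id\trun_id\tenergy\tcluster\trmsd\n")
        for m in range(n_models):
            fh.write(f"{m}\t{run_ids[m]}\t{scores[m].energy:.6f}"
                     f"\t{clusters.assignments[m]}\t{rmsds[m]:.6f}\n")
    (outdir / "report.json").write_text(
        json.dumps(report.as_dict(), indent=2, sort_keys=True) + "\n")
    _report_tsv(report, outdir / "report.tsv")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return outdir


def _report_tsv(report: select_eval.SelectionReport, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("metric\trmsd\tmodel_id\n")
        for key in ("best", "le", "le10", "le100", "lc", "lc10", "lc100"):
            val = getattr(report, f"rmsd_{key}")
            sel = report.selected.get(key.upper(), "")
            fh.write(f"{key.upper()}\t{'' if val is None else f'{val:.4f}'}\t{sel}\n")


def evaluate_against_reference(ensemble_dir: str | Path,
                               reference: str | Path | ReceptorStructure,
                               loopdef: LoopDefinition,
                               atom_mode: str = "CA",
                               K: int = 100,
                               seed: int = 0) -> select_eval.SelectionReport:
    """Re-evaluate a written ensemble against an arbitrary reference.

    Reads ``models/model_*.pdb`` and the manifest energies from a run
    directory, recomputes loop RMSDs against the given reference, reclusters,
    and rebuilds the full metric-family report (useful for comparisons with
    alternative crystal structures of the same receptor).
    """
    ensemble_dir = Path(ensemble_dir)
    if not isinstance(reference, ReceptorStructure):
        reference = read_structure(reference)
    ref_numbers = {r.number for r in reference.chain.residues}
    if not set(range(loopdef.first, loopdef.last + 1)) <= ref_numbers:
        raise ValueError("reference is missing loop residues")

    paths = sorted((ensemble_dir / "models").glob("model_*.pdb"))
    if not paths:
        raise FileNotFoundError(f"no model PDBs under {ensemble_dir}/models")
    energies: dict[int, float] = {}
    manifest = ensemble_dir / "manifest.tsv"
    if manifest.exists():
        for line in manifest.read_text().splitlines()[1:]:
            parts = line.split("\t")
            energies[int(parts[0])] = float(parts[2])

    scores, rmsds, loop_ca, ids = [], {}, [], []
    for p in paths:
        m = int(p.stem.split("_")[1]) - 1
        model = read_structure(p)
        e = energies.get(m)
        if e is None:
            e = select_eval.single_point_energy(model, model_id=m).energy
        scores.append(select_eval.ModelScore(m, e))
        sup = select_eval.superpose_excluding_loop(model, reference, loopdef)
        rmsds[m] = select_eval.loop_rmsd(model, reference, loopdef,
                                         atom_mode=atom_mode, transform=sup)
        chain = model.chain
        i0, i1 = chain.index_of(loopdef.first), chain.index_of(loopdef.last)
        loop_ca.append(np.array([r.ca.coord
                                 for r in chain.residues[i0:i1 + 1]]))
        ids.append(m)
    clusters = select_eval.cluster_models(np.array(loop_ca),
                                          K=min(K, len(ids)), seed=seed,
                                          model_ids=ids)
    return select_eval.select_models(scores, clusters, rmsds)
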