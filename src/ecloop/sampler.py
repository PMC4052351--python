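"""Metropolis Monte Carlo sampling of loop conformations.

Loop CAs move through local micromodifications -- single-CA displacement
(projected back onto the virtual-bond constraint circle), two-residue
crankshaft rotations and three-residue segment rotations -- accepted by the
asymmetric Metropolis rule min(1, exp(-dE/T + log q-ratio)).  All default
kernels are symmetric, so the proposal-ratio term is zero; it is carried
explicitly so that asymmetric kernels can be added without touching the
acceptance rule.

A production run consists of ``n_runs`` independent trajectories (seeded
``seed + k``), each recording ``snapshots_per_run`` snapshots separated by
``sweeps_per_snapshot`` sweeps (one proposal per mobile residue per sweep),
with the temperature annealed linearly from ``T_start`` to ``T_end``.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .cg_model import CA_BOND, CGChain, random_loop_conformation
from .forcefield import EnergyBreakdown, ForceFieldParams, total_energy


@dataclasses.dataclass
class MCConfig:
    n_runs: int = 2
    snapshots_per_run: int = 2000
    sweeps_per_snapshot: int = 20
    burn_in_sweeps: int = 200
    T_start: float = 2.0
    T_end: float = 1.0
    #: probabilities of {single-CA, 2-residue crankshaft, 3-residue rotation}
    move_weights: tuple[float, float, float] = (0.4, 0.3, 0.3)
    max_displacement: float = 1.0   # A; rotation amplitudes scale with this
    constrain_bonds: bool = True
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.move_weights) - 1.0) > 1e-9:
            raise ValueError("move_weights must sum to 1")
        if not (self.T_start >= self.T_end > 0):
            raise ValueError("require T_start >= T_end > 0")
        if min(self.n_runs, self.snapshots_per_run, self.sweeps_per_snapshot) < 1:
            raise ValueError("counts must be >= 1")

    @property
    def max_rotation(self) -> float:
        """Rotation amplitude (rad) matched to the displacement amplitude."""
        return self.max_displacement / CA_BOND

    def hash(self) -> str:
        return hashlib.md5(repr(self).encode()).hexdigest()[:12]


@dataclasses.dataclass
class Trajectory:
    """Snapshots of the mobile-loop CA coordinates plus their energies."""

    snapshots: list[np.ndarray]          # each (n_mobile, 3)
    energies: list[EnergyBreakdown]
    run_id: int
    seed: int
    config_hash: str
    mobile_indices: np.ndarray           # chain indices of the mobile residues


@dataclasses.dataclass
class LoopSystem:
    """A CG chain with fixed scaffold, restraint reference and SS bonds."""

    chain: CGChain                       # template; mobile coords get replaced
    scaffold_ref: np.ndarray             # (n, 3) reference CA positions
    bonds: list[tuple[int, int]]         # declared disulfides as index pairs
    ss: str = ""                         # one H/E/C label per mobile residue


def metropolis_accept(delta_E: float, T: float, log_proposal_ratio: float,
                      rng: np.random.Generator) -> bool:
    """Asymmetric Metropolis rule: accept w.p. min(1, exp(-dE/T + log q-ratio))."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    log_alpha = -delta_E / T + log_proposal_ratio
    if log_alpha >= 0:
        return True
    return rng.random() < np.exp(log_alpha)


def _project_to_circle(x: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray | None:
    """Closest point to x on the circle of positions 3.8 A from both a and b."""
    dvec = b - a
    dlen = np.linalg.norm(dvec)
    if dlen >= 2 * CA_BOND - 1e-9 or dlen < 1e-9:
        return None
    u = dvec / dlen
    m = 0.5 * (a + b)
    rho = np.sqrt(CA_BOND ** 2 - (dlen / 2) ** 2)
    w = x - m
    w_perp = w - np.dot(w, u) * u
    nw = np.linalg.norm(w_perp)
    if nw < 1e-9:
        w_perp = np.cross(u, [0.0, 0.0, 1.0])
        if np.linalg.norm(w_perp) < 1e-6:
            w_perp = np.cross(u, [0.0, 1.0, 0.0])
        nw = np.linalg.norm(w_perp)
    return m + rho * w_perp / nw


def propose_move(chain: CGChain, config: MCConfig,
                 rng: np.random.Generator) -> tuple[CGChain, float]:
    """One local micromodification of the mobile residues.

    Returns (candidate chain, log proposal ratio).  Anchors are never
    touched; the CA-CA bond constraint is restored exactly (displacements
    are projected onto the constraint circle, rotations preserve bonds by
    construction).  An infeasible draw returns the chain unchanged and
    still counts as a proposal.
    """
    mobile = chain.mobile_indices
    if mobile.size == 0:
        raise ValueError("no mobile residues to move")
    n = len(chain)
    kind = rng.choice(3, p=config.move_weights)

    # feasible sites for the rotation kernels need flanking pivots
    if kind == 1:
        sites = [i for i in mobile
                 if i + 1 < n - 1 and not chain.anchor_mask[i + 1] and i >= 1]
        if not sites:
            kind = 0
    if kind == 2:
        sites = [i for i in mobile
                 if i + 2 < n - 1 and not chain.anchor_mask[i + 1]
                 and not chain.anchor_mask[i + 2] and i >= 1]
        if not sites:
            kind = 0

    cand = chain.copy()
    if kind == 0:
        i = int(rng.choice(mobile))
        step = rng.standard_normal(3)
        step *= rng.uniform(0, config.max_displacement) / max(np.linalg.norm(step), 1e-12)
        x = chain.ca[i] + step
        if config.constrain_bonds and 0 < i < n - 1:
            x = _project_to_circle(x, chain.ca[i - 1], chain.ca[i + 1])
            if x is None:
                return cand, 0.0
        elif config.constrain_bonds:
            # terminal mobile residue: project onto the sphere of its neighbor
            j = i + 1 if i == 0 else i - 1
            v = x - chain.ca[j]
            x = chain.ca[j] + v * CA_BOND / max(np.linalg.norm(v), 1e-12)
        cand.ca[i] = x
        touched = [i - 1, i, i + 1]
    else:
        span = kind + 1  # 2 or 3 residues
        i = int(rng.choice(sites))
        pivot_a, pivot_b = chain.ca[i - 1], chain.ca[i + span]
        axis = pivot_b - pivot_a
        norm = np.linalg.norm(axis)
        if norm < 1e-9:
            return cand, 0.0
        angle = rng.uniform(-config.max_rotation, config.max_rotation)
        rot = Rotation.from_rotvec(axis / norm * angle)
        cand.ca[i:i + span] = pivot_a + rot.apply(chain.ca[i:i + span] - pivot_a)
        touched = list(range(i - 1, i + span + 1))

    cand.update_pseudoatoms([t for t in touched if 0 <= t < n])
    return cand, 0.0


def mcmc_sweeps(chain: CGChain, energy_fn: Callable[[CGChain], float],
                config: MCConfig, rng: np.random.Generator, T: float,
                n_sweeps: int,
                on_sweep: Callable[[CGChain], None] | None = None,
                ) -> tuple[CGChain, float, int, int]:
    """Run sweeps of Metropolis proposals at fixed temperature.

    One sweep = one proposal per mobile residue.  Returns the final chain,
    its energy, and the (accepted, proposed) counts.
    """
    energy = energy_fn(chain)
    n_mobile = max(1, chain.mobile_indices.size)
    accepted = proposed = 0
    for _ in range(n_sweeps):
        for _ in range(n_mobile):
            cand, log_ratio = propose_move(chain, config, rng)
            e_new = energy_fn(cand)
            proposed += 1
            if metropolis_accept(e_new - energy, T, log_ratio, rng):
                chain = cand
                energy = e_new
                accepted += 1
        if on_sweep is not None:
            on_sweep(chain)
    return chain, energy, accepted, proposed


def _init_loops(system: LoopSystem, rng: np.random.Generator) -> CGChain:
    chain = system.chain.copy()
    mask = chain.anchor_mask
    scaffold_ca = chain.ca[mask]
    n = len(chain)
    i = 0
    while i < n:
        if not mask[i]:
            j = i
            while j < n and not mask[j]:
                j += 1
            if i == 0 or j == n:
                raise ValueError("mobile segment must be flanked by anchors")
            trace = random_loop_conformation(
                (chain.ca[i - 1], chain.ca[j]), j - i,
                seed=int(rng.integers(2 ** 31)), scaffold_ca=scaffold_ca,
            )
            chain.ca[i:j] = trace
            i = j
        else:
            i += 1
    chain.update_pseudoatoms()
    return chain


def run_sampling(system: LoopSystem, ss: str, params: ForceFieldParams,
                 config: MCConfig) -> list[Trajectory]:
    """Produce the full snapshot ensemble (``n_runs`` independent runs).

    Each run starts from a fresh random loop conformation, anneals the
    temperature linearly from T_start to T_end, and records
    ``snapshots_per_run`` snapshots.  Run k is seeded ``config.seed + k``.
    """
    if ss:
        n_mobile = int((~system.chain.anchor_mask).sum())
        if len(ss) != n_mobile:
            raise ValueError("SS string length != mobile residue count")

    def energy_fn(c: CGChain) -> float:
        return total_energy(c, ss, system.scaffold_ref, system.bonds, params).total

    trajectories = []
    for k in range(config.n_runs):
        run_seed = config.seed + k
        rng = np.random.default_rng(run_seed)
        chain = _init_loops(system, rng)
        mobile = chain.mobile_indices
        chain, _, _, _ = mcmc_sweeps(chain, energy_fn, config, rng,
                                     config.T_start, config.burn_in_sweeps)
        snapshots: list[np.ndarray] = []
        energies: list[EnergyBreakdown] = []
        n_snap = config.snapshots_per_run
        for s in range(n_snap):
            frac = s / max(n_snap - 1, 1)
            T = config.T_start + frac * (config.T_end - config.T_start)
            chain, _, _, _ = mcmc_sweeps(chain, energy_fn, config, rng, T,
                                         config.sweeps_per_snapshot)
            snapshots.append(chain.ca[mobile].copy())
            energies.append(total_energy(chain, ss, system.scaffold_ref,
                                         system.bonds, params))
        trajectories.append(Trajectory(
            snapshots=snapshots, energies=energies, run_id=k, seed=run_seed,
            config_hash=config.hash(), mobile_indices=mobile.copy(),
        ))
    return trajectories


# ---------------------------------------------------------------------------
# Trajectory serialization: multi-model CA PDB + TSV sidecar
# ---------------------------------------------------------------------------

def write_trajectory(trajectories: Sequence[Trajectory], system: LoopSystem,
                     pdb_path: str | Path, tsv_path: str | Path) -> None:
    chain = system.chain
    with open(pdb_path, "w") as fh:
        model_id = 0
        for traj in trajectories:
            for snap in traj.snapshots:
                model_id += 1
                fh.write(f"MODEL {model_id:8d}\n")
                ca = chain.ca.copy()
                ca[traj.mobile_indices] = snap
                for i in range(len(chain)):
                    fh.write(
                        f"ATOM  {i + 1:5d}  CA  {chain.names[i]:<3s} A{i + 1:4d}"
                        f"    {ca[i, 0]:8.3f}{ca[i, 1]:8.3f}{ca[i, 2]:8.3f}"
                        f"  1.00  0.00           C\n"
                    )
                fh.write("ENDMDL\n")
        fh.write("END\n")
    with open(tsv_path, "w") as fh:
        fh.write("model_id\trun_id\tcontact\thbond\tss_bias\t"
                 "scaffold_restraint\tdisulfide_restraint\ttotal\n")
        model_id = 0
        for traj in trajectories:
            for e in traj.energies:
                model_id += 1
                fh.write(
                    f"{model_id}\t{traj.run_id}\t{e.contact:.6f}\t{e.hbond:.6f}"
                    f"\t{e.ss_bias:.6f}\t{e.scaffold_restraint:.6f}"
                    f"\t{e.disulfide_restraint:.6f}\t{e.total:.6f}\n"
                )
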