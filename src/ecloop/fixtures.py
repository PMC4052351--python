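"""Synthetic toy receptors and decoy ensembles.

Real seven-helix receptors require structure downloads, so the test surface
runs on idealized helical bundles: vertical ideal alpha-helices (2.3 A
radius, 1.5 A rise, 100 deg twist per residue) arranged on a circle,
connected by loops of known coordinates generated as self-avoiding bridges.
The resulting structures use the same formats and pass through the same
pipeline as real receptors; they emulate the scaffold-plus-flexible-loop
topology but none of the sequence or membrane realism of an actual GPCR.

All fixtures are bit-reproducible from (parameters, seed).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .cg_model import random_loop_conformation
from .reconstruct import ca_to_backbone, place_side_chains
from .structure_io import (Atom, Chain, DisulfideBond, LoopDefinition,
                           ONE_TO_THREE, ReceptorStructure, Residue)

HELIX_RADIUS = 2.3
HELIX_RISE = 1.5
HELIX_TWIST = 100.0  # deg per residue

#: residue palette for random sequences (no CYS: bridges are placed explicitly)
_PALETTE = "ASLVTGNFEKQD"


def ideal_helix(n: int, center: np.ndarray, z0: float, up: bool = True,
                phase: float = 0.0) -> np.ndarray:
    """CA trace of an ideal alpha-helix with a vertical axis."""
    k = np.arange(n)
    ang = np.deg2rad(HELIX_TWIST) * k + phase
    z = z0 + HELIX_RISE * k * (1 if up else -1)
    return np.stack([center[0] + HELIX_RADIUS * np.cos(ang),
                     center[1] + HELIX_RADIUS * np.sin(ang), z], axis=1)


@dataclasses.dataclass
class ToyReceptor:
    structure: ReceptorStructure         # all-atom, with native loop in place
    loop: LoopDefinition                 # the primary (extracellular) loop
    disulfides: list[DisulfideBond]
    native_loop_ca: np.ndarray           # (loop_len, 3)
    helix_flags: list[bool]


def make_toy_receptor(n_helices: int = 2, helix_len: int = 12,
                      loop_len: int = 13, seed: int = 0,
                      helix_spacing: float = 9.0,
                      with_disulfide: bool = True) -> ToyReceptor:
    """Idealized helix bundle with one known native loop across the top.

    Helices alternate up/down so the chain is contiguous; consecutive
    helices are bridged by self-avoiding loops, the first (top) bridge
    being the primary loop returned in the LoopDefinition.  Optionally one
    CYS pair (loop residue <-> helix residue near the top) is created with
    its SG atoms placed at bonding distance (synthetic geometry: the SG-SG
    separation is set to 2.04 A explicitly).
    """
    if n_helices < 2:
        raise ValueError("need at least two helices")
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3")
    rng = np.random.default_rng(seed)

    if n_helices == 2:
        centers = [np.array([0.0, 0.0]), np.array([helix_spacing, 0.0])]
    else:
        big_r = helix_spacing / (2 * np.sin(np.pi / n_helices))
        ang = 2 * np.pi * np.arange(n_helices) / n_helices
        centers = [big_r * np.array([np.cos(a), np.sin(a)]) for a in ang]

    helices = [ideal_helix(helix_len, centers[h], z0=0.0 if h % 2 == 0
                           else HELIX_RISE * (helix_len - 1),
                           up=(h % 2 == 0), phase=0.6 * h)
               for h in range(n_helices)]

    # assemble the CA trace: helix 0, bridge, helix 1, bridge, ...
    trace_parts = [helices[0]]
    flags: list[bool] = [True] * helix_len
    loop_spans: list[tuple[int, int]] = []   # residue index ranges (0-based)
    pos = helix_len
    scaffold_ca = np.concatenate(helices)
    for h in range(1, n_helices):
        a = trace_parts[-1][-1]
        b = helices[h][0]
        gap = np.linalg.norm(b - a)
        if gap > 3.9 * (loop_len + 1):
            raise ValueError(
                f"helix arrangement infeasible: {gap:.1f} A gap for a "
                f"{loop_len}-residue loop"
            )
        bridge = random_loop_conformation(
            (a, b), loop_len, seed=int(rng.integers(2 ** 31)),
            scaffold_ca=scaffold_ca)
        trace_parts.extend([bridge, helices[h]])
        loop_spans.append((pos, pos + loop_len - 1))
        flags.extend([False] * loop_len + [True] * helix_len)
        pos += loop_len + helix_len
    trace = np.concatenate(trace_parts)
    n_res = len(trace)

    seq3 = [ONE_TO_THREE[_PALETTE[int(rng.integers(len(_PALETTE)))]]
            for _ in range(n_res)]
    loop_first_idx, loop_last_idx = loop_spans[0]

    cys_pair = None
    if with_disulfide:
        helix_cys_idx = helix_len - 2       # near the top of helix 0
        # bond partner: the loop residue passing closest to it (mirrors the
        # conserved TM3-ECL2 bridge, which joins spatial neighbors)
        interior = range(loop_first_idx + 1, loop_last_idx)
        loop_cys_idx = min(
            interior,
            key=lambda i: np.linalg.norm(trace[i] - trace[helix_cys_idx]))
        seq3[loop_cys_idx] = "CYS"
        seq3[helix_cys_idx] = "CYS"
        cys_pair = (helix_cys_idx, loop_cys_idx)

    backbone = ca_to_backbone(trace, seq3)
    residues = place_side_chains(backbone)

    disulfides = []
    if cys_pair is not None:
        ra, rb = residues[cys_pair[0]], residues[cys_pair[1]]
        cb_a, cb_b = ra.atom("CB").coord, rb.atom("CB").coord
        u = cb_b - cb_a
        u = u / np.linalg.norm(u)
        m = 0.5 * (cb_a + cb_b)
        for res, sg in ((ra, m - 1.02 * u), (rb, m + 1.02 * u)):
            atom = res.atom("SG")
            if atom is None:
                res.atoms.append(Atom("SG", "S", sg))
            else:
                atom.coord = sg
        disulfides.append(DisulfideBond(cys_pair[0] + 1, cys_pair[1] + 1,
                                        "declared"))

    structure = ReceptorStructure(
        chains=[Chain("A", residues)],
        helix_flags=flags,
        declared_disulfides=disulfides,
    )
    loopdef = LoopDefinition(
        "ECL1", loop_first_idx + 1, loop_last_idx + 1,
        "".join({v: k for k, v in ONE_TO_THREE.items()}[seq3[i]]
                for i in range(loop_first_idx, loop_last_idx + 1)),
    )
    return ToyReceptor(structure, loopdef, disulfides,
                       trace[loop_first_idx:loop_last_idx + 1].copy(), flags)


def make_decoy_ensemble(native_loop: np.ndarray, n_models: int,
                        noise_scale: float, seed: int = 0,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian decoys of a native loop with generation-time RMSDs.

    Returns (ensemble (n_models, L, 3), true RMSD-to-native per model),
    where the RMSD is recorded from the applied perturbation itself.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    native = np.asarray(native_loop, dtype=float)
    rng = np.random.default_rng(seed)
    noise = noise_scale * rng.standard_normal((n_models,) + native.shape)
    ensemble = native[None, :, :] + noise
    true_rmsd = np.sqrt(np.mean(np.sum(noise ** 2, axis=2), axis=1))
    return ensemble, true_rmsd


def with_loop_trace(structure: ReceptorStructure, loopdef: LoopDefinition,
                    trace: np.ndarray) -> ReceptorStructure:
    """Copy of a structure with the loop replaced by a CA-only trace.

    Convenience for evaluating CA-level decoys with the same machinery as
    all-atom models.
    """
    import copy
    out = copy.deepcopy(structure)
    chain = out.chain
    i0 = chain.index_of(loopdef.first)
    i1 = chain.index_of(loopdef.last)
    if i1 - i0 + 1 != len(trace):
        raise ValueError("trace length does not match loop definition")
    for k, i in enumerate(range(i0, i1 + 1)):
        old = chain.residues[i]
        chain.residues[i] = Residue(old.name, old.number,
                                    [Atom("CA", "C", np.array(trace[k]))],
                                    old.icode)
    return out


@dataclasses.dataclass
class TwoStateSystem:
    """Minimal discrete system for sampler physics checks.

    Two conformations with energies (0, delta_E); proposals flip between
    them, so the stationary occupancy ratio is the Boltzmann factor
    exp(-delta_E / T).
    """

    delta_E: float
    conformations: tuple[np.ndarray, np.ndarray]

    def energy(self, state: int) -> float:
        return 0.0 if state == 0 else self.delta_E


def make_two_state_system(delta_E: float = 1.0) -> TwoStateSystem:
    return TwoStateSystem(
        delta_E=float(delta_E),
        conformations=(np.zeros((1, 3)), np.array([[3.8, 0.0, 0.0]])),
    )
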