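"""All-atom reconstruction of sampled loop CA traces.

Three stages mirror the usual coarse-grained-to-all-atom cascade: (1)
backbone (N, CA, C, O) from the CA trace by placing an ideal trans-peptide
template on every virtual CA-CA bond, orienting each peptide plane with the
local chain curvature; (2) side chains from per-residue ideal-geometry
internal coordinates with a small chi1 rotamer set, chosen greedily to
minimize steric clashes; (3) a short steepest-descent refinement of the
loop region on a clash-plus-geometry objective.

Every stage accepts an optional ``backend`` callable with the same
signature, so external reconstruction tools can be plugged in; the built-in
and external paths share the same contracts.
"""

from __future__ import annotations

import copy
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .cg_model import virtual_cbeta
from .structure_io import (Atom, LoopDefinition, ONE_TO_THREE, ReceptorStructure,
                           Residue)


def _nerf(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray,
          r: float, theta_deg: float, phi_deg: float) -> np.ndarray:
    """Place an atom bonded to p3 from bond length, angle (at p3) and
    dihedral (about p2-p3, referenced to p1)."""
    theta = np.deg2rad(theta_deg)
    phi = np.deg2rad(phi_deg)
    bc = p3 - p2
    bc /= np.linalg.norm(bc)
    n = np.cross(p2 - p1, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-r * np.cos(theta),
                  r * np.sin(theta) * np.cos(phi),
                  r * np.sin(theta) * np.sin(phi)])
    return p3 + d[0] * bc + d[1] * m + d[2] * n


def _peptide_template() -> dict[str, np.ndarray]:
    """Ideal trans-peptide unit in a canonical bond frame.

    Frame: x along CA(i)->CA(i+1), y in the peptide plane on the amide-N
    side, z the plane normal.  Bond lengths/angles: CA-C 1.52, C-N 1.33,
    N-CA 1.46 A; CA-C-N 116.2 deg, C-N-CA 121.7 deg, omega 180 deg; the
    carbonyl O bisects the remaining in-plane direction at 1.23 A.
    """
    ca1 = np.zeros(3)
    c = np.array([1.52, 0.0, 0.0])
    n = _nerf(np.array([-1.0, 1.0, 0.0]), ca1, c, 1.33, 116.2, 0.0)
    ca2 = _nerf(ca1, c, n, 1.46, 121.7, 180.0)
    d1 = (ca1 - c) / np.linalg.norm(ca1 - c)
    d2 = (n - c) / np.linalg.norm(n - c)
    od = -(d1 + d2)
    o = c + 1.23 * od / np.linalg.norm(od)
    ex = ca2 / np.linalg.norm(ca2)
    t = n - np.dot(n, ex) * ex
    ey = t / np.linalg.norm(t)
    ez = np.cross(ex, ey)
    rel = lambda p: np.array([p @ ex, p @ ey, p @ ez])
    return {"C": rel(c), "O": rel(o), "N": rel(n), "CA2": rel(ca2)}


_TEMPLATE = _peptide_template()


def ca_to_backbone(trace: np.ndarray, sequence: str | Sequence[str],
                   backend: Callable | None = None) -> list[Residue]:
    """Rebuild N, CA, C, O for every residue of a CA trace.

    The peptide template is placed on each CA-CA bond with its plane
    oriented by the local curvature normal (the orientation that reproduces
    alpha-helix O(i)...N(i+4) hydrogen-bond geometry on an ideal helix).
    Input CAs are kept exactly.
    """
    if backend is not None:
        return backend(trace, sequence)
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 2 or len(trace) < 3:
        raise ValueError("need at least 3 CA positions")
    names = ([ONE_TO_THREE[c] for c in sequence] if isinstance(sequence, str)
             else list(sequence))
    if len(names) != len(trace):
        raise ValueError("sequence length != trace length")

    n = len(trace)
    u = np.diff(trace, axis=0)
    u /= np.linalg.norm(u, axis=1)[:, None]
    coords: list[dict[str, np.ndarray]] = [dict() for _ in range(n)]
    frames = []
    for i in range(n - 1):
        xh = u[i]
        j = i if i > 0 else 1
        nrm = np.cross(u[j - 1], u[j])
        nrm = nrm - np.dot(nrm, xh) * xh
        norm = np.linalg.norm(nrm)
        if norm < 1e-8:  # locally straight chain: any perpendicular will do
            nrm = np.cross(xh, [0.0, 0.0, 1.0])
            if np.linalg.norm(nrm) < 1e-6:
                nrm = np.cross(xh, [0.0, 1.0, 0.0])
            norm = np.linalg.norm(nrm)
        yh = -nrm / norm
        zh = np.cross(xh, yh)
        M = np.stack([xh, yh, zh], axis=1)
        frames.append(M)
        coords[i]["C"] = trace[i] + M @ _TEMPLATE["C"]
        coords[i]["O"] = trace[i] + M @ _TEMPLATE["O"]
        coords[i + 1]["N"] = trace[i] + M @ (_TEMPLATE["N"] - _TEMPLATE["CA2"]) \
            + (trace[i + 1] - trace[i])
    # chain termini: the first N and last C/O have no flanking peptide unit;
    # build them from ideal internal coordinates in extended orientation
    coords[0]["N"] = _nerf(trace[1], coords[0]["C"], trace[0],
                           1.46, 111.0, 180.0)
    coords[-1]["C"] = _nerf(trace[-2], coords[-1]["N"], trace[-1],
                            1.52, 111.0, 180.0)
    coords[-1]["O"] = _nerf(coords[-1]["N"], trace[-1], coords[-1]["C"],
                            1.23, 121.0, 0.0)

    residues = []
    for i in range(n):
        atoms = [Atom("N", "N", coords[i]["N"]),
                 Atom("CA", "C", trace[i].copy()),
                 Atom("C", "C", coords[i]["C"]),
                 Atom("O", "O", coords[i]["O"])]
        residues.append(Residue(names[i], i + 1, atoms))
    return residues


# ---------------------------------------------------------------------------
# Side chains
# ---------------------------------------------------------------------------

# Internal coordinates for side-chain heavy atoms beyond CB:
# (atom, bonded_to, angle_ref, dihedral_ref, bond A, angle deg, dihedral).
# "X1" marks the rotatable chi1 dihedral (N-CA-CB-*); "X1+120"/"X1-120"
# are branches off the same carbon.  Ring dihedrals are fixed.
_SIDECHAIN_ZMAT: dict[str, list[tuple]] = {
    "GLY": [], "ALA": [],
    "SER": [("OG", "CB", "CA", "N", 1.42, 110.5, "X1")],
    "CYS": [("SG", "CB", "CA", "N", 1.81, 114.0, "X1")],
    "THR": [("OG1", "CB", "CA", "N", 1.43, 109.5, "X1"),
            ("CG2", "CB", "CA", "N", 1.52, 110.5, "X1+120")],
    "VAL": [("CG1", "CB", "CA", "N", 1.52, 110.5, "X1"),
            ("CG2", "CB", "CA", "N", 1.52, 110.5, "X1+120")],
    "LEU": [("CG", "CB", "CA", "N", 1.53, 116.3, "X1"),
            ("CD1", "CG", "CB", "CA", 1.52, 110.5, 180.0),
            ("CD2", "CG", "CB", "CA", 1.52, 110.5, 60.0)],
    "ILE": [("CG1", "CB", "CA", "N", 1.53, 110.4, "X1"),
            ("CG2", "CB", "CA", "N", 1.53, 110.5, "X1-120"),
            ("CD1", "CG1", "CB", "CA", 1.52, 113.8, 180.0)],
    "MET": [("CG", "CB", "CA", "N", 1.52, 114.1, "X1"),
            ("SD", "CG", "CB", "CA", 1.80, 112.7, 180.0),
            ("CE", "SD", "CG", "CB", 1.79, 100.9, 180.0)],
    "PRO": [("CG", "CB", "CA", "N", 1.49, 104.5, "X1"),
            ("CD", "CG", "CB", "CA", 1.50, 105.5, -30.0)],
    "PHE": [("CG", "CB", "CA", "N", 1.50, 113.8, "X1"),
            ("CD1", "CG", "CB", "CA", 1.39, 120.8, 90.0),
            ("CD2", "CG", "CB", "CA", 1.39, 120.8, -90.0),
            ("CE1", "CD1", "CG", "CB", 1.39, 120.0, 180.0),
            ("CE2", "CD2", "CG", "CB", 1.39, 120.0, 180.0),
            ("CZ", "CE1", "CD1", "CG", 1.39, 120.0, 0.0)],
    "TYR": [("CG", "CB", "CA", "N", 1.50, 113.8, "X1"),
            ("CD1", "CG", "CB", "CA", 1.39, 120.8, 90.0),
            ("CD2", "CG", "CB", "CA", 1.39, 120.8, -90.0),
            ("CE1", "CD1", "CG", "CB", 1.39, 120.0, 180.0),
            ("CE2", "CD2", "CG", "CB", 1.39, 120.0, 180.0),
            ("CZ", "CE1", "CD1", "CG", 1.39, 120.0, 0.0),
            ("OH", "CZ", "CE1", "CD1", 1.38, 120.0, 180.0)],
    "TRP": [("CG", "CB", "CA", "N", 1.50, 113.7, "X1"),
            ("CD1", "CG", "CB", "CA", 1.37, 126.9, 90.0),
            ("CD2", "CG", "CB", "CA", 1.43, 126.6, -90.0),
            ("NE1", "CD1", "CG", "CB", 1.38, 110.2, 180.0),
            ("CE2", "CD2", "CG", "CB", 1.40, 107.2, 180.0),
            ("CE3", "CD2", "CG", "CB", 1.40, 133.9, 0.0),
            ("CZ2", "CE2", "CD2", "CG", 1.40, 122.4, 180.0),
            ("CZ3", "CE3", "CD2", "CG", 1.39, 118.6, 180.0),
            ("CH2", "CZ2", "CE2", "CD2", 1.37, 117.5, 180.0)],
    "ASP": [("CG", "CB", "CA", "N", 1.52, 113.1, "X1"),
            ("OD1", "CG", "CB", "CA", 1.25, 118.9, -20.0),
            ("OD2", "CG", "CB", "CA", 1.25, 118.9, 160.0)],
    "ASN": [("CG", "CB", "CA", "N", 1.52, 112.6, "X1"),
            ("OD1", "CG", "CB", "CA", 1.23, 120.8, -20.0),
            ("ND2", "CG", "CB", "CA", 1.33, 116.4, 160.0)],
    "GLU": [("CG", "CB", "CA", "N", 1.52, 114.1, "X1"),
            ("CD", "CG", "CB", "CA", 1.52, 112.6, 180.0),
            ("OE1", "CD", "CG", "CB", 1.25, 118.9, 0.0),
            ("OE2", "CD", "CG", "CB", 1.25, 118.9, 180.0)],
    "GLN": [("CG", "CB", "CA", "N", 1.52, 114.1, "X1"),
            ("CD", "CG", "CB", "CA", 1.52, 112.6, 180.0),
            ("OE1", "CD", "CG", "CB", 1.23, 120.8, 0.0),
            ("NE2", "CD", "CG", "CB", 1.33, 116.4, 180.0)],
    "LYS": [("CG", "CB", "CA", "N", 1.52, 114.1, "X1"),
            ("CD", "CG", "CB", "CA", 1.52, 111.3, 180.0),
            ("CE", "CD", "CG", "CB", 1.52, 111.3, 180.0),
            ("NZ", "CE", "CD", "CG", 1.49, 111.9, 180.0)],
    "ARG": [("CG", "CB", "CA", "N", 1.52, 114.1, "X1"),
            ("CD", "CG", "CB", "CA", 1.52, 111.3, 180.0),
            ("NE", "CD", "CG", "CB", 1.46, 112.0, 180.0),
            ("CZ", "NE", "CD", "CG", 1.33, 124.2, 180.0),
            ("NH1", "CZ", "NE", "CD", 1.33, 120.0, 0.0),
            ("NH2", "CZ", "NE", "CD", 1.33, 120.0, 180.0)],
    "HIS": [("CG", "CB", "CA", "N", 1.49, 113.8, "X1"),
            ("ND1", "CG", "CB", "CA", 1.38, 122.7, 90.0),
            ("CD2", "CG", "CB", "CA", 1.36, 131.1, -90.0),
            ("CE1", "ND1", "CG", "CB", 1.32, 109.3, 180.0),
            ("NE2", "CD2", "CG", "CB", 1.37, 107.2, 180.0)],
}

#: chi1 rotamer candidates (deg), standard gauche-/trans/gauche+ set.
CHI1_ROTAMERS = (-60.0, 180.0, 60.0)

#: bonded or 1-3 backbone pairs across a peptide bond, exempt from clash checks
_JUNCTION_PAIRS = {("C", "N"), ("C", "CA"), ("O", "N"), ("CA", "N"), ("C", "CB")}

CLASH_DISTANCE = 1.8


def _residue_coords(res: Residue) -> dict[str, np.ndarray]:
    return {a.name: a.coord for a in res.atoms}


def count_clashes(residues: list[Residue], min_dist: float = CLASH_DISTANCE) -> int:
    """Heavy-atom pairs closer than ``min_dist``, excluding intra-residue
    and bonded/1-3 peptide-junction pairs."""
    tags = []
    pts = []
    for ri, res in enumerate(residues):
        for a in res.atoms:
            tags.append((ri, a.name))
            pts.append(a.coord)
    pts = np.asarray(pts)
    d = cdist(pts, pts)
    count = 0
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            if d[i, j] >= min_dist:
                continue
            ri, ai = tags[i]
            rj, aj = tags[j]
            if ri == rj:
                continue
            if abs(ri - rj) == 1:
                pair = (ai, aj) if ri < rj else (aj, ai)
                if pair in _JUNCTION_PAIRS:
                    continue
            count += 1
    return count


def place_side_chains(backbone: list[Residue], sequence: str | Sequence[str] | None = None,
                      backend: Callable | None = None,
                      chi1: float | None = None) -> list[Residue]:
    """Add side-chain heavy atoms to a backbone.

    CB comes from the ideal tetrahedral construction off N, CA, C; atoms
    beyond CB follow per-residue internal coordinates, trying the three
    standard chi1 rotamers in order and keeping the one with the fewest
    steric clashes against everything already placed (greedy, deterministic
    tie-break by rotamer order).  Pass ``chi1`` to force one canonical
    rotamer everywhere instead.
    """
    if backend is not None:
        return backend(backbone, sequence)
    rotamers = CHI1_ROTAMERS if chi1 is None else (float(chi1),)
    residues = [Residue(r.name, r.number,
                        [Atom(a.name, a.element, a.coord.copy()) for a in r.atoms],
                        r.icode)
                for r in backbone]
    placed_pts = [a.coord for r in residues for a in r.atoms]

    for res in residues:
        if res.name == "GLY":
            continue
        c = _residue_coords(res)
        cb = virtual_cbeta(c["N"], c["CA"], c["C"])
        res.atoms.append(Atom("CB", "C", cb))
        placed_pts.append(cb)
        zmat = _SIDECHAIN_ZMAT.get(res.name, [])
        if not zmat:
            continue
        others = np.asarray(placed_pts)
        best = None
        for chi in rotamers:
            coords = dict(c)
            coords["CB"] = cb
            new_atoms = []
            for (name, p3, p2, p1, r, theta, phi) in zmat:
                if isinstance(phi, str):
                    phi_val = chi + (120.0 if phi.endswith("+120")
                                     else -120.0 if phi.endswith("-120") else 0.0)
                else:
                    phi_val = phi
                pos = _nerf(coords[p1], coords[p2], coords[p3], r, theta, phi_val)
                coords[name] = pos
                new_atoms.append(Atom(name, name[0], pos))
            pts = np.array([a.coord for a in new_atoms])
            # clash score vs previously placed atoms (soft threshold picks
            # the least crowded rotamer; ties go to the first rotamer)
            dmin = cdist(pts, others)
            score = int((dmin < 2.5).sum())
            if best is None or score < best[0]:
                best = (score, new_atoms)
        res.atoms.extend(best[1])
        placed_pts.extend(a.coord for a in best[1])
    return residues


# ---------------------------------------------------------------------------
# Loop insertion and refinement
# ---------------------------------------------------------------------------

def insert_loop(scaffold: ReceptorStructure, loop_model: list[Residue],
                loopdef: LoopDefinition) -> ReceptorStructure:
    """Replace the loop residues of a scaffold with an all-atom loop model.

    Scaffold atoms are untouched; the loop model's residues are renumbered
    onto the loop range.  Raises on a numbering mismatch.
    """
    if len(loop_model) != loopdef.last - loopdef.first + 1:
        raise ValueError(
            f"loop model has {len(loop_model)} residues, definition spans "
            f"{loopdef.last - loopdef.first + 1}"
        )
    out = copy.deepcopy(scaffold)
    chain = out.chain
    i0 = chain.index_of(loopdef.first)
    i1 = chain.index_of(loopdef.last)
    if i1 - i0 + 1 != len(loop_model):
        raise ValueError("scaffold loop range does not match loop definition")
    new_res = []
    for k, res in enumerate(loop_model):
        new_res.append(Residue(
            res.name, loopdef.first + k,
            [Atom(a.name, a.element, a.coord.copy()) for a in res.atoms],
        ))
    chain.residues[i0:i1 + 1] = new_res
    return out


def _refine_objective(coords: np.ndarray, pairs: np.ndarray, refdist: np.ndarray,
                      clash_i: np.ndarray, clash_j: np.ndarray,
                      r0: float) -> tuple[float, np.ndarray]:
    grad = np.zeros_like(coords)
    # geometry preservation: harmonic on bonded distances
    dvec = coords[pairs[:, 0]] - coords[pairs[:, 1]]
    dist = np.linalg.norm(dvec, axis=1)
    dev = dist - refdist
    e = float(np.sum(dev ** 2))
    g = (2 * dev / np.maximum(dist, 1e-9))[:, None] * dvec
    np.add.at(grad, pairs[:, 0], g)
    np.add.at(grad, pairs[:, 1], -g)
    # soft-sphere clash
    dvec = coords[clash_i] - coords[clash_j]
    dist = np.linalg.norm(dvec, axis=1)
    close = dist < r0
    if close.any():
        dd = r0 - dist[close]
        e += float(np.sum(dd ** 2))
        g = (-2 * dd / np.maximum(dist[close], 1e-9))[:, None] * dvec[close]
        np.add.at(grad, clash_i[close], g)
        np.add.at(grad, clash_j[close], -g)
    return e, grad


def refine(model: ReceptorStructure, n_steps: int,
           loopdef: LoopDefinition | None = None,
           backend: Callable | None = None) -> ReceptorStructure:
    """Short steepest-descent relaxation of the loop region.

    Objective: soft-sphere overlap between loop atoms and everything else
    (cutoff 2.6 A) plus harmonic terms holding the loop's initial covalent
    geometry.  Only loop atoms move; the objective is non-increasing per
    step (backtracking line search).
    """
    if backend is not None:
        return backend(model, n_steps, loopdef)
    if n_steps <= 0:
        return copy.deepcopy(model)
    out = copy.deepcopy(model)
    chain = out.chain
    if loopdef is None:
        mobile_res = set(range(len(chain.residues)))
    else:
        i0 = chain.index_of(loopdef.first)
        i1 = chain.index_of(loopdef.last)
        mobile_res = set(range(i0, i1 + 1))

    atoms = []
    atom_res = []
    for ri, res in enumerate(chain.residues):
        for a in res.atoms:
            atoms.append(a)
            atom_res.append(ri)
    coords = np.array([a.coord for a in atoms])
    atom_res = np.array(atom_res)
    mobile = np.isin(atom_res, list(mobile_res))
    if not mobile.any():
        return out

    # bonded pairs to preserve: consecutive atoms within a residue plus the
    # C-N junctions, restricted to pairs touching a mobile atom
    name_index = {}
    for idx, (ri, a) in enumerate(zip(atom_res, atoms)):
        name_index[(ri, a.name)] = idx
    pairs = []
    for ri, res in enumerate(chain.residues):
        idxs = [name_index[(ri, a.name)] for a in res.atoms]
        for u, v in zip(idxs[:-1], idxs[1:]):
            pairs.append((u, v))
        if (ri + 1, "N") in name_index and (ri, "C") in name_index:
            pairs.append((name_index[(ri, "C")], name_index[(ri + 1, "N")]))
    pairs = np.array([(u, v) for u, v in pairs if mobile[u] or mobile[v]])
    refdist = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)

    # candidate clash pairs: mobile vs everything, different residues
    mob_idx = np.nonzero(mobile)[0]
    ci, cj = [], []
    d = cdist(coords[mob_idx], coords)
    for a, gi in enumerate(mob_idx):
        close = np.nonzero((d[a] < 6.0) & (atom_res != atom_res[gi]))[0]
        for gj in close:
            if gj > gi or not mobile[gj]:
                ci.append(gi)
                cj.append(gj)
    clash_i, clash_j = np.array(ci, int), np.array(cj, int)

    step = 0.05
    e, grad = _refine_objective(coords, pairs, refdist, clash_i, clash_j, 2.6)
    for _ in range(n_steps):
        grad_m = np.where(mobile[:, None], grad, 0.0)
        gnorm = np.linalg.norm(grad_m)
        if gnorm < 1e-10:
            break
        direction = -grad_m / gnorm
        trial_step = step
        for _bt in range(8):
            trial = coords + trial_step * direction
            e_new, grad_new = _refine_objective(trial, pairs, refdist,
                                                clash_i, clash_j, 2.6)
            if e_new <= e:
                coords, e, grad = trial, e_new, grad_new
                step = min(trial_step * 1.5, 0.2)
                break
            trial_step /= 2
        else:
            break
    for a, p in zip(atoms, coords):
        a.coord = p
    return out
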