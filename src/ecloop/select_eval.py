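"""Model scoring, clustering, selection, and RMSD evaluation.

The sampled ensemble is ranked two ways: by a single-point all-atom energy
and by structural clustering (K-means on loop CA coordinates after all
models are placed in the common scaffold frame).  Against a reference
structure, accuracy is summarized by the metric family

* BEST   -- lowest loop RMSD anywhere in the ensemble,
* LE     -- RMSD of the single lowest-energy model,
* LE10 / LE100 -- lowest RMSD within the 10 / 100 lowest-energy models,
* LC     -- RMSD of the largest cluster's representative,
* LC10 / LC100 -- lowest RMSD among the representatives of the 10 / 100
  largest clusters.

Loop RMSD is always computed after superposing the model onto the
reference on the non-loop CAs only (no re-fitting on the loop itself), so
it measures loop placement within the receptor frame, not loop shape alone.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation
from sklearn.cluster import KMeans

from .structure_io import LoopDefinition, ReceptorStructure

BACKBONE_SET = ("N", "CA", "C", "O")


@dataclasses.dataclass
class ModelScore:
    model_id: int
    energy: float

    def __post_init__(self):
        if not np.isfinite(self.energy):
            raise ValueError(f"model {self.model_id}: non-finite energy")


@dataclasses.dataclass
class ClusterResult:
    assignments: dict[int, int]       # model_id -> cluster rank (0 = largest)
    cluster_sizes: list[int]          # descending
    representatives: list[int]        # model_id closest to each centroid
    n_dropped: int = 0                # empty clusters removed


@dataclasses.dataclass
class SelectionReport:
    rmsd_best: float | None = None
    rmsd_le: float | None = None
    rmsd_le10: float | None = None
    rmsd_le100: float | None = None
    rmsd_lc: float | None = None
    rmsd_lc10: float | None = None
    rmsd_lc100: float | None = None
    selected: dict[str, int] = dataclasses.field(default_factory=dict)
    candidates: dict[str, list[int]] = dataclasses.field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "rmsd_best": self.rmsd_best, "rmsd_le": self.rmsd_le,
            "rmsd_le10": self.rmsd_le10, "rmsd_le100": self.rmsd_le100,
            "rmsd_lc": self.rmsd_lc, "rmsd_lc10": self.rmsd_lc10,
            "rmsd_lc100": self.rmsd_lc100, "selected": self.selected,
        }


# ---------------------------------------------------------------------------
# Single-point energy
# ---------------------------------------------------------------------------

#: bonded / 1-3 atom-name pairs across a peptide junction (i, i+1)
_JUNCTION = {("C", "N"), ("C", "CA"), ("O", "N"), ("CA", "N"), ("C", "CB")}

DEFAULT_WEIGHTS = {"lj": 1.0, "clash": 10.0, "torsion": 1.0}


def _flatten(structure: ReceptorStructure):
    coords, res_idx, names = [], [], []
    for ri, res in enumerate(structure.chain.residues):
        for a in res.atoms:
            coords.append(a.coord)
            res_idx.append(ri)
            names.append(a.name)
    return np.asarray(coords), np.asarray(res_idx), names


def _dihedral(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    return float(np.arctan2(np.dot(np.cross(b1, v), w), np.dot(v, w)))


def single_point_energy(model: ReceptorStructure,
                        weights: dict | None = None,
                        model_id: int = 0,
                        backend: Callable | None = None) -> ModelScore:
    """Deterministic all-atom score: 12-6 nonbonded + soft clash + an
    omega-regularity term (lower is better, arbitrary units).

    Pairs within a residue and bonded/1-3 pairs across peptide junctions
    are excluded.  A ``backend`` callable with the same signature may
    replace the built-in score.
    """
    if backend is not None:
        return backend(model, weights, model_id)
    w = dict(DEFAULT_WEIGHTS)
    if weights:
        w.update(weights)
    coords, res_idx, names = _flatten(model)
    n = len(coords)
    d = cdist(coords, coords)
    ii, jj = np.triu_indices(n, k=1)
    keep = res_idx[ii] != res_idx[jj]
    adjacent = np.abs(res_idx[ii] - res_idx[jj]) == 1
    junction = np.zeros(len(ii), dtype=bool)
    adj_idx = np.nonzero(adjacent)[0]
    for k in adj_idx:
        a, b = (ii[k], jj[k]) if res_idx[ii[k]] < res_idx[jj[k]] else (jj[k], ii[k])
        if (names[a], names[b]) in _JUNCTION:
            junction[k] = True
    keep &= ~junction
    r = np.clip(d[ii, jj][keep], 1.5, None)

    sigma = 3.2
    sr6 = (sigma / r) ** 6
    e_lj = float(np.sum(4 * 0.2 * (sr6 ** 2 - sr6) * (r < 10.0)))
    close = r < 2.6
    e_clash = float(np.sum((2.6 - r[close]) ** 2))

    e_torsion = 0.0
    chain = model.chain.residues
    for i in range(len(chain) - 1):
        a = {x.name: x.coord for x in chain[i].atoms}
        b = {x.name: x.coord for x in chain[i + 1].atoms}
        if all(k in a for k in ("CA", "C")) and all(k in b for k in ("N", "CA")):
            omega = _dihedral(a["CA"], a["C"], b["N"], b["CA"])
            e_torsion += 1.0 - np.cos(omega - np.pi)

    energy = w["lj"] * e_lj + w["clash"] * e_clash + w["torsion"] * e_torsion
    return ModelScore(model_id=model_id, energy=float(energy))


# ---------------------------------------------------------------------------
# Superposition and RMSD
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Superposition:
    """Rigid transform x -> R (x - com_mobile) + com_ref, plus its fit RMSD."""

    rotation: np.ndarray
    com_mobile: np.ndarray
    com_ref: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return (np.asarray(coords) - self.com_mobile) @ self.rotation.T + self.com_ref


def _loop_keys(loopdef: LoopDefinition) -> set[int]:
    return set(range(loopdef.first, loopdef.last + 1))


def _ca_map(structure: ReceptorStructure) -> dict[int, np.ndarray]:
    return {r.number: r.ca.coord for r in structure.chain.residues}


def superpose_excluding_loop(model: ReceptorStructure,
                             reference: ReceptorStructure,
                             loopdef: LoopDefinition | Sequence[LoopDefinition],
                             ) -> Superposition:
    """Least-squares (Kabsch) fit of the model onto the reference using the
    CAs of all residues outside the loop(s)."""
    loops = [loopdef] if isinstance(loopdef, LoopDefinition) else list(loopdef)
    excluded: set[int] = set()
    for l in loops:
        excluded |= _loop_keys(l)
    ca_m = _ca_map(model)
    ca_r = _ca_map(reference)
    common = sorted((set(ca_m) & set(ca_r)) - excluded)
    if len(common) < 3:
        raise ValueError("need at least 3 common non-loop CA atoms")
    x = np.array([ca_m[k] for k in common])
    y = np.array([ca_r[k] for k in common])
    com_x, com_y = x.mean(axis=0), y.mean(axis=0)
    rot, rssd = Rotation.align_vectors(y - com_y, x - com_x)
    rmsd = rssd / np.sqrt(len(common))
    return Superposition(rot.as_matrix(), com_x, com_y, float(rmsd))


def loop_rmsd(model: ReceptorStructure, reference: ReceptorStructure,
              loopdef: LoopDefinition, atom_mode: str = "CA",
              transform: Superposition | None = None) -> float:
    """RMSD over the loop atoms, in the frame fixed by the scaffold fit.

    ``atom_mode``: CA, backbone (N/CA/C/O) or heavy (all heavy atoms).  No
    re-fitting is done on the loop; pass ``transform`` to reuse a
    scaffold superposition (computed here when omitted).
    """
    if transform is None:
        transform = superpose_excluding_loop(model, reference, loopdef)
    keys = _loop_keys(loopdef)

    def collect(structure):
        out = {}
        for res in structure.chain.residues:
            if res.number not in keys:
                continue
            for a in res.atoms:
                if a.element.startswith("H"):
                    continue
                if atom_mode == "CA" and a.name != "CA":
                    continue
                if atom_mode == "backbone" and a.name not in BACKBONE_SET:
                    continue
                out[(res.number, a.name)] = a.coord
        return out

    am, ar = collect(model), collect(reference)
    if set(am) != set(ar):
        missing = set(am) ^ set(ar)
        raise ValueError(f"loop atom sets differ between model and reference "
                         f"({len(missing)} unmatched)")
    if not am:
        raise ValueError("loop not present in both structures")
    keys_sorted = sorted(am)
    x = transform.apply(np.array([am[k] for k in keys_sorted]))
    y = np.array([ar[k] for k in keys_sorted])
    return float(np.sqrt(np.mean(np.sum((x - y) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# Clustering and selection
# ---------------------------------------------------------------------------

def cluster_models(ensemble: np.ndarray | Sequence[np.ndarray], K: int = 100,
                   seed: int = 0,
                   model_ids: Sequence[int] | None = None) -> ClusterResult:
    """K-means over flattened loop CA coordinate vectors.

    ``ensemble``: (n_models, n_loop_res, 3) or a list of (n_loop_res, 3)
    arrays, all pre-superposed on the common scaffold frame.  K shrinks to
    the ensemble size when larger; empty clusters are dropped and counted.
    """
    X = np.asarray(ensemble, dtype=float)
    if X.ndim == 3:
        X = X.reshape(len(X), -1)
    n = len(X)
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K={K} exceeds ensemble size {n}")
    ids = list(model_ids) if model_ids is not None else list(range(n))

    km = KMeans(n_clusters=K, random_state=seed, n_init=10)
    labels = km.fit_predict(X)

    sizes = np.bincount(labels, minlength=K)
    nonempty = np.nonzero(sizes)[0]
    order = nonempty[np.lexsort((nonempty, -sizes[nonempty]))]
    rank = {int(lab): r for r, lab in enumerate(order)}

    assignments = {ids[i]: rank[int(labels[i])] for i in range(n)}
    reps = []
    for lab in order:
        members = np.nonzero(labels == lab)[0]
        dist = np.linalg.norm(X[members] - km.cluster_centers_[lab], axis=1)
        reps.append(ids[members[np.argmin(dist)]])
    return ClusterResult(
        assignments=assignments,
        cluster_sizes=[int(sizes[lab]) for lab in order],
        representatives=reps,
        n_dropped=int(K - len(order)),
    )


def select_models(scores: Sequence[ModelScore], clusters: ClusterResult,
                  rmsds: dict[int, float] | None = None) -> SelectionReport:
    """Build the BEST/LE/LC metric family report.

    Ties (equal energies, equal RMSDs) break toward the smaller model id.
    Candidate sets truncate to the ensemble size when smaller than 10/100.
    """
    by_energy = sorted(scores, key=lambda s: (s.energy, s.model_id))
    le_sets = {
        "LE": [by_energy[0].model_id],
        "LE10": [s.model_id for s in by_energy[:10]],
        "LE100": [s.model_id for s in by_energy[:100]],
    }
    lc_sets = {
        "LC": clusters.representatives[:1],
        "LC10": clusters.representatives[:10],
        "LC100": clusters.representatives[:100],
    }
    report = SelectionReport(candidates={**le_sets, **lc_sets})
    report.selected["LE"] = le_sets["LE"][0]
    report.selected["LC"] = lc_sets["LC"][0]
    if rmsds is None:
        return report

    def best_of(ids):
        sel = min(ids, key=lambda m: (rmsds[m], m))
        return rmsds[sel], sel

    report.rmsd_best, best_id = best_of([s.model_id for s in scores])
    report.selected["BEST"] = best_id
    report.rmsd_le = rmsds[le_sets["LE"][0]]
    report.rmsd_lc = rmsds[lc_sets["LC"][0]]
    for key, ids in (("LE10", le_sets["LE10"]), ("LE100", le_sets["LE100"]),
                     ("LC10", lc_sets["LC10"]), ("LC100", lc_sets["LC100"])):
        val, sel = best_of(ids)
        setattr(report, f"rmsd_{key.lower()}", val)
        report.selected[key] = sel
    return report
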