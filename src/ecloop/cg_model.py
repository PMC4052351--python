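"""Coarse-grained chain representation and geometry.

Each residue is reduced to up to four interaction centers: the alpha carbon
(CA), the beta carbon (CB), the side-chain center of mass (SC) and the
midpoint of the virtual CA-CA bond to the next residue (MID).  Coordinates
are continuous Cartesian positions (Angstrom) with a fixed virtual CA-CA
bond of 3.8 A; the original lattice discretization of this representation
is deliberately not reproduced (its geometry is not public), so sampling
moves act on continuous CA traces and pseudoatoms are rebuilt from local
frames.

The scaffold/loop split is carried by ``anchor_mask``: anchor (scaffold)
residues never move during sampling.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .structure_io import ATOMIC_MASS, ReceptorStructure, LoopDefinition

#: Virtual CA-CA bond length (A) and tolerance on it.
CA_BOND = 3.8
BOND_TOL = 0.12

# CA->CB offset in the local frame (u along CA(i+1)-CA(i-1), v = outward
# bisector of the CA triangle, w = u x v), derived once from the ideal
# tetrahedral beta-carbon on an ideal alpha-helix backbone.  The w component
# encodes the L-amino-acid side.
_CB_LOCAL = np.array([0.543, 0.764, 1.341])

#: CA -> side-chain-center offsets (u, v, w components, A) per residue type,
#: calibrated once against ideal-geometry side chains in the canonical
#: chi1 = -60 rotamer on an ideal helix.  GLY uses the virtual beta-carbon
#: position.  Coil conformations reproduce these less faithfully; the
#: contact well widths absorb that slack.
SC_FRAME_OFFSETS = {
    "GLY": tuple(_CB_LOCAL),
    "ALA": (0.527, 0.773, 1.314),
    "ARG": (-0.365, 3.119, 3.737),
    "ASN": (-0.509, 1.733, 1.881),
    "ASP": (-0.510, 1.747, 1.900),
    "CYS": (-0.347, 1.611, 1.830),
    "GLN": (0.141, 2.144, 2.814),
    "GLU": (0.140, 2.161, 2.836),
    "HIS": (-1.007, 2.129, 2.248),
    "ILE": (0.405, 1.645, 1.808),
    "LEU": (-0.364, 1.499, 2.211),
    "LYS": (-0.243, 2.538, 3.074),
    "MET": (-0.144, 2.296, 2.828),
    "PHE": (-1.127, 2.358, 2.280),
    "PRO": (-0.468, 1.469, 1.156),
    "SER": (-0.043, 1.277, 1.596),
    "THR": (0.224, 0.828, 1.834),
    "TRP": (-1.158, 3.264, 1.995),
    "TYR": (-1.461, 2.687, 2.473),
    "VAL": (0.287, 0.757, 1.855),
}


@dataclasses.dataclass
class CGResidue:
    """View of one coarse-grained residue (positions in A)."""

    name: str
    ca: np.ndarray
    cb: np.ndarray
    sc: np.ndarray
    mid: np.ndarray | None  # None for the chain-terminal residue


class CGChain:
    """Array-backed coarse-grained chain.

    Parameters
    ----------
    ca : (n, 3) array of CA positions.
    names : list of 3-letter residue names.
    anchor_mask : (n,) bool array, True = fixed scaffold residue.
    cb, sc : optional (n, 3) arrays; rebuilt from the trace when omitted.
    """

    def __init__(self, ca, names, anchor_mask, cb=None, sc=None):
        self.ca = np.asarray(ca, dtype=float)
        self.names = list(names)
        self.anchor_mask = np.asarray(anchor_mask, dtype=bool)
        n = len(self.names)
        if self.ca.shape != (n, 3) or self.anchor_mask.shape != (n,):
            raise ValueError("inconsistent CGChain array shapes")
        if cb is None or sc is None:
            self.cb = np.empty_like(self.ca)
            self.sc = np.empty_like(self.ca)
            self.update_pseudoatoms()
        else:
            self.cb = np.asarray(cb, dtype=float).copy()
            self.sc = np.asarray(sc, dtype=float).copy()

    def __len__(self) -> int:
        return len(self.names)

    @property
    def mid(self) -> np.ndarray:
        """Midpoints of consecutive CA-CA virtual bonds, shape (n-1, 3)."""
        return 0.5 * (self.ca[:-1] + self.ca[1:])

    @property
    def mobile_indices(self) -> np.ndarray:
        return np.nonzero(~self.anchor_mask)[0]

    @property
    def residues(self) -> list[CGResidue]:
        mids = self.mid
        return [
            CGResidue(self.names[i], self.ca[i], self.cb[i], self.sc[i],
                      mids[i] if i < len(self) - 1 else None)
            for i in range(len(self))
        ]

    def copy(self) -> "CGChain":
        out = CGChain.__new__(CGChain)
        out.ca = self.ca.copy()
        out.cb = self.cb.copy()
        out.sc = self.sc.copy()
        out.names = list(self.names)
        out.anchor_mask = self.anchor_mask.copy()
        return out

    # -- geometry ----------------------------------------------------------

    def bond_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.ca, axis=0), axis=1)

    def check_bonds(self, tol: float = BOND_TOL) -> None:
        b = self.bond_lengths()
        if b.size and (b.min() < CA_BOND - 0.02 - tol or b.max() > CA_BOND + 0.02 + tol):
            raise ValueError(
                f"CA-CA bond out of range: min {b.min():.3f}, max {b.max():.3f} A"
            )

    def update_pseudoatoms(self, indices=None) -> None:
        """(Re)build CB/SC for the given residue indices (default: all).

        Deterministic function of the CA trace and the sequence.
        """
        n = len(self)
        if n < 3:
            raise ValueError("pseudoatom frames need at least 3 residues")
        if indices is None:
            indices = range(n)
        for i in indices:
            if i < 0 or i >= n:
                continue
            j = min(max(i, 1), n - 2)  # frame center (clamped for termini)
            u = self.ca[j + 1] - self.ca[j - 1]
            nu = np.linalg.norm(u)
            u = u / nu if nu > 1e-9 else np.array([1.0, 0.0, 0.0])
            v = self.ca[j] - 0.5 * (self.ca[j - 1] + self.ca[j + 1])
            v = v - np.dot(v, u) * u
            nv = np.linalg.norm(v)
            if nv < 1e-6:
                v = np.array([0.0, 0.0, 1.0]) - u[2] * u
                nv = np.linalg.norm(v)
                if nv < 1e-6:
                    v = np.array([0.0, 1.0, 0.0]) - u[1] * u
                    nv = np.linalg.norm(v)
            v /= nv
            w = np.cross(u, v)
            frame = np.stack([u, v, w], axis=1)
            self.cb[i] = self.ca[i] + frame @ _CB_LOCAL
            off = SC_FRAME_OFFSETS.get(self.names[i], SC_FRAME_OFFSETS["ALA"])
            self.sc[i] = self.ca[i] + frame @ np.asarray(off)


# ---------------------------------------------------------------------------
# Conversion from all-atom
# ---------------------------------------------------------------------------

def virtual_cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal-geometry virtual beta carbon from backbone N, CA, C positions.

    Standard tetrahedral construction used throughout coarse-grained
    modeling for glycine and for validating side-chain frames.
    """
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * cc + ca


def allatom_to_cg(structure: ReceptorStructure,
                  loops: list[LoopDefinition] | None = None) -> CGChain:
    """Reduce the primary chain of an all-atom structure to CG centers.

    SC is the mass-weighted center of the side-chain heavy atoms (CB and
    beyond); ALA's SC is its CB; GLY gets a virtual CB (and SC == CB) from
    the backbone frame.  Residues inside ``loops`` are marked mobile.
    """
    chain = structure.chain
    n = len(chain.residues)
    ca = np.empty((n, 3))
    cb = np.empty((n, 3))
    sc = np.empty((n, 3))
    names = []
    for i, res in enumerate(chain.residues):
        names.append(res.name)
        ca[i] = res.ca.coord
        atom_cb = res.atom("CB")
        if atom_cb is None:
            n_at, c_at = res.atom("N"), res.atom("C")
            if n_at is None or c_at is None:
                raise ValueError(
                    f"residue {res.name} {res.number}: no CB and incomplete backbone"
                )
            cb[i] = virtual_cbeta(n_at.coord, ca[i], c_at.coord)
        else:
            cb[i] = atom_cb.coord
        heavy = [a for a in res.side_chain_atoms() if not a.element.startswith("H")]
        if heavy:
            masses = np.array([ATOMIC_MASS.get(a.element, 12.011) for a in heavy])
            coords = np.array([a.coord for a in heavy])
            sc[i] = masses @ coords / masses.sum()
        else:
            sc[i] = cb[i]

    anchor = np.ones(n, dtype=bool)
    if loops:
        for loop in loops:
            i0 = chain.index_of(loop.first)
            i1 = chain.index_of(loop.last)
            anchor[i0:i1 + 1] = False
    return CGChain(ca, names, anchor, cb=cb, sc=sc)


def rebuild_pseudoatoms(trace: np.ndarray, sequence: list[str] | str,
                        anchor_mask=None) -> CGChain:
    """Build a CGChain from a CA trace, placing CB/SC from local frames.

    ``sequence`` may be 3-letter names or a one-letter string.  Deterministic
    given the trace.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 2 or trace.shape[0] < 3:
        raise ValueError("trace must contain at least 3 residues")
    if isinstance(sequence, str):
        from .structure_io import ONE_TO_THREE
        names = [ONE_TO_THREE[c] for c in sequence]
    else:
        names = list(sequence)
    if len(names) != trace.shape[0]:
        raise ValueError("sequence length does not match trace length")
    if anchor_mask is None:
        anchor_mask = np.zeros(len(names), dtype=bool)
    chain = CGChain(trace, names, anchor_mask)
    chain.check_bonds()
    return chain


# ---------------------------------------------------------------------------
# Random loop initialization
# ---------------------------------------------------------------------------

def random_loop_conformation(anchors: tuple[np.ndarray, np.ndarray],
                             n_res: int,
                             seed: int,
                             scaffold_ca: np.ndarray | None = None,
                             clearance: float = 3.0,
                             max_retries: int = 5000) -> np.ndarray:
    """Self-avoiding random CA walk bridging two fixed anchors.

    Generates ``n_res`` mobile CA positions between the pre-loop and
    post-loop anchor CAs, with every CA-CA step exactly 3.8 A, no mobile CA
    closer than ``clearance`` to any scaffold CA, and non-adjacent mobile
    CAs at least ``clearance`` apart.  Reproducible for a fixed seed.
    """
    a = np.asarray(anchors[0], dtype=float)
    b = np.asarray(anchors[1], dtype=float)
    gap = float(np.linalg.norm(b - a))
    if gap > 3.9 * (n_res + 1):
        raise ValueError(
            f"anchors {gap:.1f} A apart are unreachable with {n_res + 1} "
            f"bonds of {CA_BOND} A"
        )
    rng = np.random.default_rng(seed)
    scaffold = None if scaffold_ca is None else np.asarray(scaffold_ca, float)

    def clear(p: np.ndarray, placed: list[np.ndarray]) -> bool:
        if scaffold is not None and scaffold.size:
            if np.min(np.linalg.norm(scaffold - p, axis=1)) < clearance:
                return False
        # self-avoidance against non-adjacent placed residues
        for q in placed[:-1]:
            if np.linalg.norm(q - p) < clearance:
                return False
        return True

    for _ in range(max_retries):
        placed: list[np.ndarray] = []
        p = a
        ok = True
        for k in range(1, n_res):  # residues 1..n-1; last one closes the bridge
            remaining = n_res - k  # mobile residues still to place after this one
            dmax = CA_BOND * (remaining + 1) - 0.05
            for _try in range(60):
                if rng.random() < 0.5:
                    d = b - p
                    nd = np.linalg.norm(d)
                    step = d / nd + 0.9 * rng.standard_normal(3)
                else:
                    step = rng.standard_normal(3)
                step *= CA_BOND / np.linalg.norm(step)
                cand = p + step
                dist_b = np.linalg.norm(cand - b)
                lo = 0.5 if remaining > 1 else clearance
                if lo <= dist_b <= dmax and clear(cand, placed + [p]):
                    break
            else:
                ok = False
                break
            placed.append(cand)
            p = cand
        if not ok:
            continue
        # close the bridge: last residue on the two-sphere intersection circle
        d = np.linalg.norm(b - p) if n_res > 1 else gap
        start = p if n_res > 1 else a
        d = float(np.linalg.norm(b - start))
        if not (0.1 < d < 2 * CA_BOND):
            continue
        u = (b - start) / d
        rho = np.sqrt(CA_BOND ** 2 - (d / 2) ** 2)
        m = 0.5 * (start + b)
        e1 = np.cross(u, [0.0, 0.0, 1.0])
        if np.linalg.norm(e1) < 1e-6:
            e1 = np.cross(u, [0.0, 1.0, 0.0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(u, e1)
        for _try in range(60):
            theta = rng.uniform(0, 2 * np.pi)
            cand = m + rho * (np.cos(theta) * e1 + np.sin(theta) * e2)
            if clear(cand, placed + [start]):
                placed.append(cand)
                break
        else:
            continue
        return np.array(placed)

    raise RuntimeError(
        f"could not place a {n_res}-residue loop after {max_retries} attempts "
        f"(anchor gap {gap:.1f} A, clearance {clearance} A)"
    )
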