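"""Coarse-grained energy function.

Four terms, all dimensionless (units of the simulation temperature):

* pairwise side-chain contacts from a knowledge-based 20x20 table, with a
  square-well form (hard-core repulsion below ``r_rep``, table energy inside
  the contact well, zero beyond);
* a main-chain hydrogen-bond proxy rewarding CA pairs at H-bond-compatible
  distance and orientation;
* a secondary-structure bias: flat-bottom harmonic windows on CA(n)-CA(n+2)
  and CA(n)-CA(n+4) distances for loop residues labeled H or E;
* harmonic restraints pinning scaffold CAs to their reference positions and
  pulling declared disulfide-bonded CYS side chains to a bonding distance.

Loop-specific softening: for pairs involving a loop residue the attractive
well half-width is scaled by ``d1`` (default 0.5) and the repulsive wall is
divided by ``d2`` (default 1.5).  ``d1 = d2 = 1`` recovers the unsoftened
term.  When disulfide bridges are declared, the CYS-CYS table entry is set
to zero so that the statistical contact term cannot bias cysteines toward
more than binary contacts; the bonded pairs are held by the strong
restraint instead.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .cg_model import CGChain
from .structure_io import AA1, THREE_TO_ONE

_AA_INDEX = {a: i for i, a in enumerate(AA1)}


def load_contact_table(path: str | Path | None = None) -> np.ndarray:
    """Load a 20x20 symmetric contact-energy table from TSV.

    Default: the packaged table, a smooth hydrophobicity-derived surrogate
    with the shape of published residue-contact statistical potentials
    (hydrophobic pairs attract, polar pairs mildly repel).
    """
    if path is None:
        with resources.files("ecloop.data").joinpath("contact_table.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t", index_col=0)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    df = df.loc[list(AA1), list(AA1)]
    table = df.to_numpy(dtype=float)
    if not np.allclose(table, table.T):
        raise ValueError("contact table must be symmetric")
    return table


def save_contact_table(table: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(table, index=list(AA1), columns=list(AA1)).to_csv(path, sep="\t")


@dataclasses.dataclass
class ForceFieldParams:
    """All tunable constants of the coarse-grained energy."""

    contact_table: np.ndarray = None          # (20, 20), units of kT
    r_rep: float = 3.0                        # hard-core SC-SC distance, A
    r_well: tuple[float, float] = (4.0, 6.5)  # contact well (inner, outer), A
    e_rep: float = 5.0                        # repulsive penalty height
    d1: float = 0.5                           # loop well-width scale
    d2: float = 1.5                           # loop repulsive-wall softening
    w_hb: float = 1.0                         # H-bond reward magnitude
    hb_range: tuple[float, float] = (4.6, 5.6)  # CA-CA H-bond distance gate, A
    hb_cos_max: float = 0.75                  # orientation gate on |cos|
    ss_wells: dict = dataclasses.field(default_factory=lambda: {
        "H": ((5.1, 5.8), (5.8, 6.7)),
        "E": ((6.3, 7.2), (11.5, 13.5)),
    })
    k_ss: float = 1.0                         # SS-bias spring, kT/A^2
    k_scaffold: float = 10.0                  # scaffold CA restraint, kT/A^2
    k_ss_bond: float = 100.0                  # disulfide restraint, kT/A^2
    r_ss_target: float = 3.2                  # target SC-SC distance for bonded CYS, A

    def __post_init__(self):
        if self.contact_table is None:
            self.contact_table = load_contact_table()
        self.contact_table = np.asarray(self.contact_table, dtype=float)
        if self.contact_table.shape != (20, 20):
            raise ValueError("contact table must be 20x20")
        if not np.allclose(self.contact_table, self.contact_table.T):
            raise ValueError("contact table must be symmetric")
        if self.d1 <= 0 or self.d2 <= 0:
            raise ValueError("d1 and d2 must be positive")
        for k in (self.k_ss, self.k_scaffold, self.k_ss_bond):
            if k < 0:
                raise ValueError("force constants must be non-negative")

    def declare_disulfides(self) -> "ForceFieldParams":
        """Return a copy with the CYS-CYS statistical contact zeroed."""
        table = self.contact_table.copy()
        c = _AA_INDEX["C"]
        table[c, c] = 0.0
        return dataclasses.replace(self, contact_table=table)


@dataclasses.dataclass
class EnergyBreakdown:
    contact: float
    hbond: float
    ss_bias: float
    scaffold_restraint: float
    disulfide_restraint: float

    @property
    def total(self) -> float:
        return (self.contact + self.hbond + self.ss_bias
                + self.scaffold_restraint + self.disulfide_restraint)


def _aa_indices(chain: CGChain) -> np.ndarray:
    return np.array([_AA_INDEX[THREE_TO_ONE.get(name, "A")]
                     for name in chain.names])


def contact_energy(chain: CGChain, params: ForceFieldParams,
                   loop_mask: np.ndarray | None = None) -> float:
    """Square-well side-chain contact energy over pairs with |i-j| >= 2."""
    if loop_mask is None:
        loop_mask = ~chain.anchor_mask
    n = len(chain)
    d = cdist(chain.sc, chain.sc)
    ii, jj = np.triu_indices(n, k=2)
    dist = d[ii, jj]
    looppair = loop_mask[ii] | loop_mask[jj]

    r_in, r_out = params.r_well
    center = 0.5 * (r_in + r_out)
    halfw = np.where(looppair, params.d1, 1.0) * 0.5 * (r_out - r_in)
    e_rep = np.where(looppair, params.e_rep / params.d2, params.e_rep)

    idx = _aa_indices(chain)
    table_vals = params.contact_table[idx[ii], idx[jj]]

    energy = np.where(
        dist < params.r_rep, e_rep,
        np.where(np.abs(dist - center) <= halfw, table_vals, 0.0),
    )
    return float(energy.sum())


def _hbond_pairs(chain: CGChain, params: ForceFieldParams) -> list[tuple[float, int, int]]:
    ca = chain.ca
    n = len(chain)
    if n < 5:
        return []
    # local chain direction (undefined at termini; those residues are skipped)
    b = np.zeros((n, 3))
    b[1:-1] = ca[2:] - ca[:-2]
    norms = np.linalg.norm(b, axis=1)
    ok = norms > 1e-9
    b[ok] /= norms[ok, None]

    d = cdist(ca, ca)
    lo, hi = params.hb_range
    ii, jj = np.nonzero(np.triu(np.ones((n, n), bool), k=3) & (d >= lo) & (d <= hi))
    pairs = []
    for i, j in zip(ii, jj):
        if not (0 < i < n - 1 and 0 < j < n - 1):
            continue
        r = ca[j] - ca[i]
        r = r / np.linalg.norm(r)
        if abs(np.dot(r, b[i])) <= params.hb_cos_max and \
           abs(np.dot(r, b[j])) <= params.hb_cos_max:
            pairs.append((d[i, j], int(i), int(j)))
    return pairs


def hbond_energy(chain: CGChain, params: ForceFieldParams) -> float:
    """Main-chain hydrogen-bond proxy on the CA trace.

    Rewards -w_hb for every pair |i-j| >= 3 with CA distance inside the
    H-bond gate and local virtual-bond orientation compatible with a
    backbone H-bond; greedy distance-ordered matching limits each residue
    to two partners (one donor and one acceptor slot).
    """
    pairs = sorted(_hbond_pairs(chain, params))
    slots = np.zeros(len(chain), dtype=int)
    count = 0
    for _, i, j in pairs:
        if slots[i] < 2 and slots[j] < 2:
            slots[i] += 1
            slots[j] += 1
            count += 1
    return -params.w_hb * count


def ss_bias_energy(chain: CGChain, ss: str, params: ForceFieldParams,
                   loop_mask: np.ndarray | None = None) -> float:
    """Flat-bottom harmonic bias toward H/E short-range CA distances.

    ``ss`` has one H/E/C label per mobile (loop) residue, in chain order.
    """
    if loop_mask is None:
        loop_mask = ~chain.anchor_mask
    loop_idx = np.nonzero(loop_mask)[0]
    if len(ss) != len(loop_idx):
        raise ValueError(
            f"SS string length {len(ss)} != number of loop residues {len(loop_idx)}"
        )
    ca = chain.ca
    n = len(chain)
    energy = 0.0
    for label, i in zip(ss, loop_idx):
        wells = params.ss_wells.get(label)
        if wells is None:  # C: no bias
            continue
        for k, (lo, hi) in zip((2, 4), wells):
            if i + k >= n:
                continue
            dist = float(np.linalg.norm(ca[i + k] - ca[i]))
            if dist < lo:
                energy += params.k_ss * (lo - dist) ** 2
            elif dist > hi:
                energy += params.k_ss * (dist - hi) ** 2
    return energy


def restraint_energy(chain: CGChain, scaffold_ref: np.ndarray,
                     bonds: list[tuple[int, int]],
                     params: ForceFieldParams,
                     restrained: np.ndarray | None = None,
                     ) -> tuple[float, float]:
    """Harmonic scaffold + disulfide restraints.

    ``scaffold_ref`` is an (n, 3) reference CA array covering at least the
    restrained residues; ``bonds`` are chain-index pairs of declared
    disulfide CYS.  Returns (scaffold term, disulfide term).
    """
    if restrained is None:
        restrained = chain.anchor_mask
    scaffold_ref = np.asarray(scaffold_ref, dtype=float)
    dev = chain.ca[restrained] - scaffold_ref[restrained]
    e_scaffold = params.k_scaffold * float(np.sum(dev * dev))

    e_ss = 0.0
    for i, j in bonds:
        if chain.names[i] != "CYS" or chain.names[j] != "CYS":
            raise ValueError(f"disulfide bond ({i}, {j}) references a non-CYS residue")
        dist = float(np.linalg.norm(chain.sc[i] - chain.sc[j]))
        e_ss += params.k_ss_bond * (dist - params.r_ss_target) ** 2
    return e_scaffold, e_ss


def total_energy(chain: CGChain, ss: str, scaffold_ref: np.ndarray,
                 bonds: list[tuple[int, int]], params: ForceFieldParams,
                 loop_mask: np.ndarray | None = None) -> EnergyBreakdown:
    """Full energy breakdown; ``total`` is the exact sum of the components."""
    e_scaffold, e_ssbond = restraint_energy(chain, scaffold_ref, bonds, params)
    return EnergyBreakdown(
        contact=contact_energy(chain, params, loop_mask),
        hbond=hbond_energy(chain, params),
        ss_bias=ss_bias_energy(chain, ss, params, loop_mask),
        scaffold_restraint=e_scaffold,
        disulfide_restraint=e_ssbond,
    )
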