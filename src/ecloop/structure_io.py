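"""Structure input/output and loop bookkeeping.

Reads and writes receptor structures in PDB format, partitions a chain into
transmembrane-helix scaffold and loop regions, detects or accepts declared
disulfide bridges, and validates loop definitions (residue ranges plus
one-letter sequences, both ends inclusive).

Residue identity is the author identity: (chain id, residue number,
insertion code).  Ranges such as 139-172 are inclusive on both ends.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import protein_letters_3to1_extended as _3TO1
from Bio.PDB import PDBParser

AA3 = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]
AA1 = "ARNDCQEGHILKMFPSTWYV"
THREE_TO_ONE = {a3: _3TO1[a3.capitalize()] for a3 in AA3}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# average atomic masses for the elements occurring in amino-acid heavy atoms
ATOMIC_MASS = {"C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "SE": 78.97}

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


@dataclasses.dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinates must be 3 finite numbers")


@dataclasses.dataclass
class Residue:
    name: str          # 3-letter code
    number: int        # author residue number
    atoms: list[Atom] = dataclasses.field(default_factory=list)
    icode: str = ""

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom:
        a = self.atom("CA")
        if a is None:
            raise ValueError(f"residue {self.name} {self.number}{self.icode} has no CA")
        return a

    @property
    def key(self) -> tuple[int, str]:
        return (self.number, self.icode)

    def side_chain_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.name not in BACKBONE_ATOMS]


@dataclasses.dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = dataclasses.field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def index_of(self, number: int, icode: str = "") -> int:
        for i, r in enumerate(self.residues):
            if r.number == number and r.icode == icode:
                return i
        raise KeyError(f"residue {number}{icode} not in chain {self.chain_id}")


@dataclasses.dataclass
class DisulfideBond:
    """A Cys-Cys bridge, identified by author residue numbers."""

    residue_a: int
    residue_b: int
    provenance: str = "declared"  # "detected" | "declared"
    icode_a: str = ""
    icode_b: str = ""

    def __post_init__(self):
        if (self.residue_a, self.icode_a) == (self.residue_b, self.icode_b):
            raise ValueError("disulfide bond must join two distinct residues")


@dataclasses.dataclass
class LoopDefinition:
    """One extracellular loop: residue range (inclusive) plus sequence."""

    loop_id: str
    first: int
    last: int
    sequence: str

    def __post_init__(self):
        if self.last < self.first:
            raise ValueError(f"{self.loop_id}: last residue < first residue")
        bad = set(self.sequence) - set(AA1)
        if bad:
            raise ValueError(f"{self.loop_id}: non-standard letters {sorted(bad)}")


@dataclasses.dataclass
class ReceptorStructure:
    """All-atom receptor with an optional per-residue helix annotation."""

    chains: list[Chain]
    helix_flags: list[bool] | None = None      # aligned with primary chain
    declared_disulfides: list[DisulfideBond] = dataclasses.field(default_factory=list)

    @property
    def chain(self) -> Chain:
        """Primary (first) chain; the seven-helix bundle lives here."""
        return self.chains[0]

    def validate(self) -> None:
        for ch in self.chains:
            if not ch.residues:
                raise ValueError(f"chain {ch.chain_id} is empty")
            numbers = [(r.number, r.icode) for r in ch.residues]
            if any(numbers[i][0] > numbers[i + 1][0] for i in range(len(numbers) - 1)):
                raise ValueError(f"chain {ch.chain_id}: residue numbers not increasing")
            for r in ch.residues:
                r.ca  # raises if missing


def loop_length(loop: LoopDefinition) -> int:
    """Inclusive residue count of a loop; raises if it disagrees with the sequence."""
    span = loop.last - loop.first + 1
    if span != len(loop.sequence):
        raise ValueError(
            f"{loop.loop_id}: numbering {loop.first}-{loop.last} spans {span} residues "
            f"but sequence has {len(loop.sequence)}"
        )
    return span


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def read_structure(path: str | Path, format: str = "pdb") -> ReceptorStructure:
    """Read an all-atom structure from a PDB file.

    Only residues possessing a CA atom are retained; alternate locations
    resolve to the highest-occupancy conformer (ties: first encountered);
    insertion codes are preserved as part of residue identity.  SSBOND
    records become declared disulfide bonds.
    """
    if format != "pdb":
        raise ValueError(f"unsupported format: {format}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bio = parser.get_structure("x", str(path))
    try:
        model = next(bio.get_models())
    except StopIteration:
        raise ValueError(f"{path}: no ATOM records") from None

    chains: list[Chain] = []
    for bchain in model:
        residues = []
        for bres in bchain:
            hetflag, resseq, icode = bres.id
            if hetflag.strip():
                continue  # heteroatoms/ligands out of scope
            atoms = []
            for batom in bres:
                if batom.is_disordered():
                    alts = sorted(
                        batom.disordered_get_list(),
                        key=lambda a: -a.get_occupancy(),
                    )
                    batom = alts[0]
                elem = (batom.element or batom.get_name()[0]).upper()
                # PDB coordinates carry 3 decimals; round away the float32
                # representation noise of the parser
                coord = np.round(np.asarray(batom.get_coord(), dtype=float), 3)
                atoms.append(
                    Atom(batom.get_name(), elem, coord,
                         float(batom.get_occupancy() or 1.0))
                )
            if any(a.name == "CA" for a in atoms):
                residues.append(Residue(bres.get_resname(), resseq, atoms,
                                        icode.strip()))
        if residues:
            chains.append(Chain(bchain.id.strip() or "A", residues))

    if not chains:
        raise ValueError(f"{path}: no chain with CA atoms")

    structure = ReceptorStructure(chains=chains,
                                  declared_disulfides=_parse_ssbond(path))
    structure.validate()
    return structure


def _parse_ssbond(path: Path) -> list[DisulfideBond]:
    # Bio.PDB's header parser does not expose SSBOND records, so the fixed
    # columns (PDB format v3.3) are read here directly.
    bonds = []
    with open(path) as fh:
        for line in fh:
            if not line.startswith("SSBOND"):
                continue
            try:
                num_a = int(line[17:21])
                num_b = int(line[31:35])
            except ValueError:
                continue
            ic_a = line[21].strip() if len(line) > 21 else ""
            ic_b = line[35].strip() if len(line) > 35 else ""
            bonds.append(DisulfideBond(num_a, num_b, "declared", ic_a, ic_b))
    return bonds


_PDB_ATOM = (
    "ATOM  {serial:5d} {name:<4s}{altloc:1s}{resname:<3s} {chain:1s}"
    "{resseq:4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
    "          {element:>2s}\n"
)


def write_structure(structure: ReceptorStructure, path: str | Path) -> None:
    """Write a structure as PDB (ATOM/TER records, SSBOND for declared bridges)."""
    with open(path, "w") as fh:
        for i, b in enumerate(structure.declared_disulfides, start=1):
            fh.write(
                f"SSBOND {i:3d} CYS {structure.chain.chain_id:1s} {b.residue_a:4d}"
                f"{b.icode_a or ' '}   CYS {structure.chain.chain_id:1s} "
                f"{b.residue_b:4d}{b.icode_b or ' '}\n"
            )
        serial = 1
        for ch in structure.chains:
            for res in ch.residues:
                for atom in res.atoms:
                    name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
                    fh.write(_PDB_ATOM.format(
                        serial=serial, name=name, altloc=" ", resname=res.name,
                        chain=ch.chain_id, resseq=res.number,
                        icode=res.icode or " ",
                        x=atom.coord[0], y=atom.coord[1], z=atom.coord[2],
                        occ=atom.occupancy, b=0.0, element=atom.element,
                    ))
                    serial += 1
            fh.write(f"TER   {serial:5d}      {ch.residues[-1].name:<3s} "
                     f"{ch.chain_id}{ch.residues[-1].number:4d}\n")
            serial += 1
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Disulfide detection
# ---------------------------------------------------------------------------

def detect_disulfides(structure: ReceptorStructure,
                      sg_cutoff: float = 2.5) -> list[DisulfideBond]:
    """Detect Cys-Cys bridges from Sgamma-Sgamma distances.

    Greedy closest-pair matching below ``sg_cutoff`` (Angstrom); each CYS
    participates in at most one bond.
    """
    if sg_cutoff <= 0:
        raise ValueError("sg_cutoff must be positive")
    cys = []
    for ch in structure.chains:
        for r in ch.residues:
            if r.name == "CYS":
                sg = r.atom("SG")
                if sg is not None:
                    cys.append((r, sg.coord))
    pairs = []
    for i in range(len(cys)):
        for j in range(i + 1, len(cys)):
            d = float(np.linalg.norm(cys[i][1] - cys[j][1]))
            if d < sg_cutoff:
                pairs.append((d, i, j))
    pairs.sort()
    used: set[int] = set()
    bonds = []
    for _, i, j in pairs:
        if i in used or j in used:
            continue
        used.update((i, j))
        ra, rb = cys[i][0], cys[j][0]
        bonds.append(DisulfideBond(ra.number, rb.number, "detected",
                                   ra.icode, rb.icode))
    return bonds


# ---------------------------------------------------------------------------
# Loop boundary selection
# ---------------------------------------------------------------------------

def select_loop_boundaries(structure: ReceptorStructure,
                           helix_annotation: Sequence[bool] | None = None,
                           ) -> list[LoopDefinition]:
    """Delimit loops as maximal non-helix runs flanked by helix on both sides.

    ``helix_annotation`` is one flag per residue of the primary chain (True =
    part of a transmembrane helix).  When omitted, the structure's own
    annotation is used, falling back to the geometric rule of
    :func:`geometric_helix_flags`.
    """
    chain = structure.chain
    flags = helix_annotation
    if flags is None:
        flags = structure.helix_flags
    if flags is None:
        flags = geometric_helix_flags(structure)
    flags = list(flags)
    if len(flags) != len(chain.residues):
        raise ValueError("annotation length does not match residue count")

    loops: list[LoopDefinition] = []
    n = len(flags)
    i = 0
    while i < n:
        if not flags[i]:
            j = i
            while j < n and not flags[j]:
                j += 1
            if i > 0 and j < n:  # flanked by helix on both sides
                seq = "".join(THREE_TO_ONE.get(r.name, "X")
                              for r in chain.residues[i:j])
                loops.append(LoopDefinition(
                    loop_id=f"ECL{len(loops) + 1}",
                    first=chain.residues[i].number,
                    last=chain.residues[j - 1].number,
                    sequence=seq,
                ))
            i = j
        else:
            i += 1
    if not loops:
        raise ValueError("no inter-helix segment found")
    return loops


def geometric_helix_flags(structure: ReceptorStructure,
                          d_range: tuple[float, float] = (4.5, 6.5),
                          ) -> list[bool]:
    """Geometric surrogate for an H-bond-network helix assignment.

    A five-residue window starting at n is helical when both the
    CA(n)-CA(n+3) and CA(n)-CA(n+4) distances fall within ``d_range``
    (default 4.5-6.5 Angstrom, bracketing ideal alpha-helix geometry); every
    residue covered by at least one helical window is flagged.  This stands
    in for a hydrogen-bond-network analysis of the transmembrane helices.
    """
    chain = structure.chain
    ca = np.array([r.ca.coord for r in chain.residues])
    n = len(ca)
    flags = [False] * n
    lo, hi = d_range
    for i in range(n - 4):
        d3 = np.linalg.norm(ca[i] - ca[i + 3])
        d4 = np.linalg.norm(ca[i] - ca[i + 4])
        if lo <= d3 <= hi and lo <= d4 <= hi:
            for k in range(i, i + 5):
                flags[k] = True
    return flags


# ---------------------------------------------------------------------------
# Loop-definition TSV interface
# ---------------------------------------------------------------------------

def write_loop_definitions(loops: Iterable[LoopDefinition],
                           path: str | Path) -> None:
    df = pd.DataFrame(
        [(l.loop_id, l.first, l.last, l.sequence) for l in loops],
        columns=["loop_id", "first", "last", "sequence"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_loop_definitions(path: str | Path) -> list[LoopDefinition]:
    df = pd.read_csv(path, sep="\t", dtype={"sequence": str})
    return [
        LoopDefinition(str(row.loop_id), int(row.first), int(row.last),
                       str(row.sequence))
        for row in df.itertuples()
    ]
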