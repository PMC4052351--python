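"""All-atom reconstruction: backbone, side chains, insertion, refinement."""

import copy

import numpy as np
import pytest

from ecloop.cg_model import random_loop_conformation
from ecloop.fixtures import ideal_helix
from ecloop.reconstruct import (ca_to_backbone, count_clashes, insert_loop,
                                place_side_chains, refine)
from ecloop.structure_io import LoopDefinition


def _geometry(residues):
    out = []
    for i, res in enumerate(residues):
        c = {a.name: a.coord for a in res.atoms}
        entry = {
            "n_ca": np.linalg.norm(c["N"] - c["CA"]),
            "ca_c": np.linalg.norm(c["CA"] - c["C"]),
        }
        if i + 1 < len(residues):
            nxt = {a.name: a.coord for a in residues[i + 1].atoms}
            entry["c_n"] = np.linalg.norm(c["C"] - nxt["N"])
        out.append(entry)
    return out


class TestBackbone:
    def test_peptide_geometry_within_tolerances(self, ideal_helix_trace):
        bb = ca_to_backbone(ideal_helix_trace, ["ALA"] * 12)
        for g in _geometry(bb):
            assert abs(g["n_ca"] - 1.46) < 0.06
            assert abs(g["ca_c"] - 1.52) < 0.06
            if "c_n" in g:
                assert abs(g["c_n"] - 1.33) < 0.06

    def test_helix_backbone_forms_i_i4_hydrogen_bonds(self, ideal_helix_trace):
        bb = ca_to_backbone(ideal_helix_trace, ["ALA"] * 12)
        for i in range(1, 7):
            d = np.linalg.norm(bb[i].atom("O").coord - bb[i + 4].atom("N").coord)
            assert d < 3.5

    @pytest.mark.parametrize("seed", range(10))
    def test_ca_positions_preserved_on_random_traces(self, seed):
        b = np.array([15.0, 2.0, -1.0])
        trace = random_loop_conformation((np.zeros(3), b), 10, seed=seed)
        trace = np.vstack([np.zeros(3), trace, b])
        bb = ca_to_backbone(trace, ["GLY"] * 12)
        dev = max(np.linalg.norm(r.atom("CA").coord - t)
                  for r, t in zip(bb, trace))
        assert dev <= 0.5

    def test_two_residue_trace_raises(self):
        with pytest.raises(ValueError):
            ca_to_backbone(np.array([[0, 0, 0], [3.8, 0, 0]], float), "AA")


class TestSideChains:
    def test_poly_ala_cb_is_ideal_tetrahedral(self, ideal_helix_trace):
        bb = ca_to_backbone(ideal_helix_trace, ["ALA"] * 12)
        aa = place_side_chains(bb)
        for res in aa:
            c = {a.name: a.coord for a in res.atoms}
            v1 = c["N"] - c["CA"]
            v2 = c["C"] - c["CA"]
            cb = c["CB"] - c["CA"]
            ang = lambda u, v: np.rad2deg(np.arccos(
                np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))))
            assert 1.4 < np.linalg.norm(cb) < 1.7
            assert abs(ang(v1, cb) - 109.5) < 8
            assert abs(ang(v2, cb) - 109.5) < 8
            # L-chirality: CB consistently on one side of the N-CA-C plane
            assert np.dot(np.cross(v1, v2), cb) > 0

    def test_poly_gly_gets_no_side_chain_atoms(self, ideal_helix_trace):
        bb = ca_to_backbone(ideal_helix_trace, ["GLY"] * 12)
        aa = place_side_chains(bb)
        for res in aa:
            assert {a.name for a in res.atoms} == {"N", "CA", "C", "O"}

    def test_extended_mixed_decapeptide_is_clash_free(self):
        seq = ["MET", "LYS", "TRP", "PHE", "ARG", "GLU", "TYR", "ILE",
               "HIS", "GLN"]
        trace = np.stack([np.arange(10) * 3.8, np.zeros(10), np.zeros(10)],
                         axis=1)
        aa = place_side_chains(ca_to_backbone(trace, seq))
        assert count_clashes(aa) == 0

    def test_deterministic(self, ideal_helix_trace):
        seq = ["LEU", "SER", "PHE", "LYS", "ASP", "TRP", "VAL", "GLN",
               "ILE", "ARG", "THR", "ASN"]
        a = place_side_chains(ca_to_backbone(ideal_helix_trace, seq))
        b = place_side_chains(ca_to_backbone(ideal_helix_trace, seq))
        for ra, rb in zip(a, b):
            for x, y in zip(ra.atoms, rb.atoms):
                assert np.array_equal(x.coord, y.coord)


class TestInsertLoop:
    def _native_loop(self, toy):
        chain = toy.structure.chain
        i0 = chain.index_of(toy.loop.first)
        i1 = chain.index_of(toy.loop.last)
        return copy.deepcopy(chain.residues[i0:i1 + 1])

    def test_native_loop_round_trip(self, toy):
        out = insert_loop(toy.structure, self._native_loop(toy), toy.loop)
        for ra, rb in zip(toy.structure.chain.residues, out.chain.residues):
            for x, y in zip(ra.atoms, rb.atoms):
                assert np.abs(x.coord - y.coord).max() < 1e-3

    def test_scaffold_atoms_bit_unchanged(self, toy):
        loop = self._native_loop(toy)
        for res in loop:
            for a in res.atoms:
                a.coord = a.coord + 1.0
        out = insert_loop(toy.structure, loop, toy.loop)
        keys = set(range(toy.loop.first, toy.loop.last + 1))
        for ra, rb in zip(toy.structure.chain.residues, out.chain.residues):
            if ra.number in keys:
                continue
            for x, y in zip(ra.atoms, rb.atoms):
                assert np.array_equal(x.coord, y.coord)

    def test_numbering_mismatch_raises(self, toy):
        loop = self._native_loop(toy)[:-1]
        with pytest.raises(ValueError):
            insert_loop(toy.structure, loop, toy.loop)


class TestRefine:
    def test_zero_steps_is_identity(self, toy):
        out = refine(toy.structure, 0, toy.loop)
        for ra, rb in zip(toy.structure.chain.residues, out.chain.residues):
            for x, y in zip(ra.atoms, rb.atoms):
                assert np.array_equal(x.coord, y.coord)

    def test_scaffold_fixed_and_clashes_not_worsened(self, toy):
        start = count_clashes(toy.structure.chain.residues, min_dist=2.2)
        out = refine(toy.structure, 10, toy.loop)
        assert count_clashes(out.chain.residues, min_dist=2.2) <= start
        keys = set(range(toy.loop.first, toy.loop.last + 1))
        for ra, rb in zip(toy.structure.chain.residues, out.chain.residues):
            if ra.number in keys:
                continue
            for x, y in zip(ra.atoms, rb.atoms):
                assert np.array_equal(x.coord, y.coord)


def test_full_cascade_preserves_ca_trace():
    """Backbone + side chains + refinement keep the sampled CA positions."""
    b = np.array([14.0, 1.0, 3.0])
    trace = random_loop_conformation((np.zeros(3), b), 11, seed=3)
    trace = np.vstack([np.zeros(3), trace, b])
    seq = ["ALA", "SER", "LEU", "GLY", "PHE", "LYS", "THR", "ASP", "VAL",
           "ASN", "GLN", "GLU", "ALA"]
    model = place_side_chains(ca_to_backbone(trace, seq))
    ca = np.array([r.atom("CA").coord for r in model])
    rmsd = np.sqrt(np.mean(np.sum((ca - trace) ** 2, axis=1)))
    assert rmsd <= 0.5
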