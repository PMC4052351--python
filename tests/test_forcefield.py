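"""Energy terms: contacts, H-bond proxy, SS bias, restraints."""

import dataclasses

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ecloop.cg_model import CGChain, rebuild_pseudoatoms
from ecloop.forcefield import (ForceFieldParams, contact_energy, hbond_energy,
                               load_contact_table, restraint_energy,
                               ss_bias_energy, total_energy)
from ecloop.fixtures import ideal_helix
from ecloop.structure_io import AA1, THREE_TO_ONE


@pytest.fixture(scope="module")
def params():
    return ForceFieldParams()


def brute_force_contact(chain, params, loop_mask):
    """Independent O(n^2) python-loop reimplementation of the contact sum."""
    idx = {a: i for i, a in enumerate(AA1)}
    r_in, r_out = params.r_well
    center, halfw0 = 0.5 * (r_in + r_out), 0.5 * (r_out - r_in)
    total = 0.0
    n = len(chain)
    for i in range(n):
        for j in range(i + 2, n):
            r = float(np.linalg.norm(chain.sc[i] - chain.sc[j]))
            looppair = loop_mask[i] or loop_mask[j]
            halfw = halfw0 * (params.d1 if looppair else 1.0)
            if r < params.r_rep:
                total += params.e_rep / (params.d2 if looppair else 1.0)
            elif abs(r - center) <= halfw:
                ai = idx[THREE_TO_ONE[chain.names[i]]]
                aj = idx[THREE_TO_ONE[chain.names[j]]]
                total += params.contact_table[ai, aj]
    return total


def _straight_chain(n, names=None, spacing=3.8):
    trace = np.stack([np.arange(n) * spacing, np.zeros(n), np.zeros(n)], axis=1)
    return rebuild_pseudoatoms(trace, names or ["ALA"] * n)


class TestContact:
    def test_zero_when_all_pairs_beyond_well(self, params):
        chain = _straight_chain(6, spacing=3.8)
        chain.sc[:] = chain.ca + np.array([0, 50, 0]) * np.arange(6)[:, None]
        assert contact_energy(chain, params) == 0.0

    def test_pair_inside_well_scores_table_entry(self, params):
        chain = _straight_chain(4)
        # put sc of residues 0 and 3 at 5.0 A (inside default well 4.0-6.5)
        chain.sc[:] = [[0, 100, 0], [0, 200, 0], [0, 300, 0], [5.0, 100, 0]]
        loop_mask = np.zeros(4, bool)
        e = contact_energy(chain, params, loop_mask)
        ala = AA1.index("A")
        assert e == pytest.approx(params.contact_table[ala, ala])

    def test_declared_cys_pair_contributes_zero(self):
        params = ForceFieldParams().declare_disulfides()
        chain = _straight_chain(4, names=["CYS", "ALA", "ALA", "CYS"])
        chain.sc[:] = [[0, 100, 0], [0, 200, 0], [0, 300, 0], [5.0, 100, 0]]
        assert contact_energy(chain, params, np.zeros(4, bool)) == 0.0

    def test_matches_brute_force_exactly(self, toy_cg, params):
        loop_mask = ~toy_cg.anchor_mask
        fast = contact_energy(toy_cg, params, loop_mask)
        slow = brute_force_contact(toy_cg, params, loop_mask)
        assert fast == pytest.approx(slow, abs=1e-12)

    def test_d1_d2_unity_recovers_unsoftened_term(self, toy_cg):
        soft = ForceFieldParams()
        hard = ForceFieldParams(d1=1.0, d2=1.0)
        none_mobile = np.zeros(len(toy_cg), bool)
        # with no loop residues the softening never applies
        assert contact_energy(toy_cg, soft, none_mobile) == \
            contact_energy(toy_cg, hard, none_mobile)
        # and d1=d2=1 with a loop equals treating everything as scaffold
        assert contact_energy(toy_cg, hard, ~toy_cg.anchor_mask) == \
            contact_energy(toy_cg, hard, none_mobile)


class TestHBond:
    def test_extended_chain_scores_zero(self, params):
        assert hbond_energy(_straight_chain(10), params) == 0.0

    def test_ideal_helix_rewarded(self, params):
        chain = rebuild_pseudoatoms(ideal_helix(10, np.zeros(2), 0.0),
                                    ["ALA"] * 10)
        e = hbond_energy(chain, params)
        assert e < 0
        assert e <= -5 * params.w_hb  # at least 5 gated pairs on the helix

    def test_rigid_invariance(self, toy_cg, params):
        rot = Rotation.from_euler("zxz", [1.0, 0.5, -0.3])
        moved = toy_cg.copy()
        moved.ca = rot.apply(moved.ca) + 5.0
        moved.sc = rot.apply(moved.sc) + 5.0
        moved.cb = rot.apply(moved.cb) + 5.0
        assert hbond_energy(moved, params) == \
            pytest.approx(hbond_energy(toy_cg, params), abs=1e-9)


class TestSSBias:
    def test_all_coil_is_zero(self, toy_cg, params):
        assert ss_bias_energy(toy_cg, "C" * 13, params) == 0.0

    def test_ideal_helix_loop_with_H_labels_is_zero(self, params):
        trace = ideal_helix(13, np.zeros(2), 0.0)
        chain = rebuild_pseudoatoms(trace, ["ALA"] * 13)
        chain.anchor_mask[:] = False
        assert ss_bias_energy(chain, "H" * 13, params) == 0.0

    def test_extended_loop_with_H_labels_penalized(self, params):
        chain = _straight_chain(13)
        chain.anchor_mask[:] = False
        assert ss_bias_energy(chain, "H" * 13, params) > 0.0

    def test_wrong_label_count_raises(self, toy_cg, params):
        with pytest.raises(ValueError):
            ss_bias_energy(toy_cg, "C" * 12, params)


class TestRestraints:
    def test_zero_at_reference_and_target(self, toy_cg):
        params = ForceFieldParams()
        e_sc, e_ss = restraint_energy(toy_cg, toy_cg.ca.copy(), [], params)
        assert e_sc == 0.0 and e_ss == 0.0

    def test_hand_computed_harmonic(self, toy_cg):
        params = ForceFieldParams(k_scaffold=100.0)
        ref = toy_cg.ca.copy()
        moved = toy_cg.copy()
        anchor = int(np.nonzero(moved.anchor_mask)[0][0])
        moved.ca[anchor, 0] += 0.5
        e_sc, _ = restraint_energy(moved, ref, [], params)
        assert e_sc == pytest.approx(25.0)

    def test_non_cys_bond_raises(self, toy_cg):
        ala = next(i for i, n in enumerate(toy_cg.names) if n != "CYS")
        cys = next(i for i, n in enumerate(toy_cg.names) if n == "CYS")
        with pytest.raises(ValueError):
            restraint_energy(toy_cg, toy_cg.ca.copy(), [(ala, cys)],
                             ForceFieldParams())


class TestTotal:
    def _bonds(self, toy):
        return [(b.residue_a - 1, b.residue_b - 1) for b in toy.disulfides]

    def test_breakdown_sums_to_total(self, toy, toy_cg):
        params = ForceFieldParams().declare_disulfides()
        e = total_energy(toy_cg, "C" * 13, toy_cg.ca.copy(), self._bonds(toy),
                         params)
        parts = (e.contact + e.hbond + e.ss_bias + e.scaffold_restraint
                 + e.disulfide_restraint)
        assert e.total == pytest.approx(parts, rel=1e-9)

    def test_zero_weights_zero_total(self, toy, toy_cg):
        params = ForceFieldParams(contact_table=np.zeros((20, 20)), e_rep=0.0,
                                  w_hb=0.0, k_ss=0.0, k_scaffold=0.0,
                                  k_ss_bond=0.0)
        e = total_energy(toy_cg, "H" * 13, toy_cg.ca.copy(), self._bonds(toy),
                         params)
        assert e.total == 0.0

    def test_linear_in_scaffold_constant(self, toy, toy_cg):
        moved = toy_cg.copy()
        moved.ca[toy_cg.anchor_mask] += 0.3
        ref = toy_cg.ca.copy()
        p1 = ForceFieldParams(k_scaffold=5.0)
        p2 = ForceFieldParams(k_scaffold=10.0)
        e1 = total_energy(moved, "C" * 13, ref, [], p1)
        e2 = total_energy(moved, "C" * 13, ref, [], p2)
        assert e2.scaffold_restraint == pytest.approx(2 * e1.scaffold_restraint)
        for field in ("contact", "hbond", "ss_bias", "disulfide_restraint"):
            assert getattr(e1, field) == getattr(e2, field)

    def test_rigid_invariance_of_total(self, toy, toy_cg):
        params = ForceFieldParams().declare_disulfides()
        bonds = self._bonds(toy)
        ref = toy_cg.ca.copy()
        rot = Rotation.from_euler("xyz", [0.2, 1.2, -0.7])
        shift = np.array([4.0, 4.0, -9.0])
        moved = toy_cg.copy()
        for arr in (moved.ca, moved.cb, moved.sc):
            arr[:] = rot.apply(arr) + shift
        e0 = total_energy(toy_cg, "C" * 13, ref, bonds, params)
        e1 = total_energy(moved, "C" * 13, rot.apply(ref) + shift, bonds, params)
        assert e1.total == pytest.approx(e0.total, abs=1e-8)


def test_contact_table_is_symmetric_and_editable(tmp_path):
    table = load_contact_table()
    assert table.shape == (20, 20)
    assert np.allclose(table, table.T)
    from ecloop.forcefield import save_contact_table
    table2 = table.copy()
    table2[0, 1] = table2[1, 0] = -9.9
    path = tmp_path / "custom.tsv"
    save_contact_table(table2, path)
    assert np.allclose(load_contact_table(path), table2)


def test_asymmetric_table_rejected():
    bad = np.zeros((20, 20))
    bad[0, 1] = 1.0
    with pytest.raises(ValueError):
        ForceFieldParams(contact_table=bad)
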