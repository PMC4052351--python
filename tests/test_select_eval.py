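"""Scoring, superposition, RMSD, clustering and the metric family."""

import copy
import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ecloop.fixtures import make_decoy_ensemble, with_loop_trace
from ecloop.select_eval import (ClusterResult, ModelScore, cluster_models,
                                loop_rmsd, select_models, single_point_energy,
                                superpose_excluding_loop)


class TestSinglePointEnergy:
    def test_identical_models_identical_energies(self, toy):
        e1 = single_point_energy(toy.structure).energy
        e2 = single_point_energy(copy.deepcopy(toy.structure)).energy
        assert e1 == e2

    def test_introduced_clash_raises_energy(self, toy):
        clashed = copy.deepcopy(toy.structure)
        res = clashed.chain.residues
        # move one loop CA onto a scaffold atom (1.0 A separation)
        i = clashed.chain.index_of(toy.loop.first + 2)
        target = res[0].ca.coord
        for a in res[i].atoms:
            a.coord = a.coord - res[i].ca.coord + target + np.array([1.0, 0, 0])
        assert single_point_energy(clashed).energy > \
            single_point_energy(toy.structure).energy

    def test_translation_invariance(self, toy):
        moved = copy.deepcopy(toy.structure)
        for r in moved.chain.residues:
            for a in r.atoms:
                a.coord = a.coord + np.array([100.0, -50.0, 25.0])
        assert single_point_energy(moved).energy == \
            pytest.approx(single_point_energy(toy.structure).energy, abs=1e-9)


class TestSuperposition:
    def test_identical_structures(self, toy):
        sup = superpose_excluding_loop(toy.structure, toy.structure, toy.loop)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-6)

    def test_recovers_known_rotation(self, toy):
        rot = Rotation.from_euler("xyz", [0.3, -0.5, 1.1])
        shift = np.array([5.0, -3.0, 2.0])
        ref = copy.deepcopy(toy.structure)
        for r in ref.chain.residues:
            for a in r.atoms:
                a.coord = rot.apply(a.coord) + shift
        sup = superpose_excluding_loop(toy.structure, ref, toy.loop)
        assert np.allclose(sup.rotation, rot.as_matrix(), atol=1e-6)
        assert sup.rmsd < 1e-9

    def test_optimal_among_random_rotations(self, toy):
        """Kabsch beats 2000 random rigid fits on the same atom sets."""
        perturbed = copy.deepcopy(toy.structure)
        rng = np.random.default_rng(0)
        for r in perturbed.chain.residues:
            for a in r.atoms:
                a.coord = a.coord + 0.3 * rng.standard_normal(3)
        sup = superpose_excluding_loop(perturbed, toy.structure, toy.loop)
        keys = set(range(toy.loop.first, toy.loop.last + 1))
        x = np.array([r.ca.coord for r in perturbed.chain.residues
                      if r.number not in keys])
        y = np.array([r.ca.coord for r in toy.structure.chain.residues
                      if r.number not in keys])
        xc, yc = x - x.mean(0), y - y.mean(0)
        best = min(np.sqrt(np.mean(np.sum(
            (xc @ Rotation.random(random_state=s).as_matrix().T - yc) ** 2,
            axis=1))) for s in range(2000))
        assert sup.rmsd <= best + 1e-12

    def test_too_few_common_atoms_raises(self, toy):
        whole = [copy.deepcopy(toy.loop)]
        whole[0].first = 1
        whole[0].last = len(toy.structure.chain.residues)
        whole[0].sequence = "A" * whole[0].last
        with pytest.raises(ValueError):
            superpose_excluding_loop(toy.structure, toy.structure, whole)


class TestLoopRMSD:
    def test_identical_loop_is_zero(self, toy):
        assert loop_rmsd(toy.structure, toy.structure, toy.loop) == \
            pytest.approx(0.0, abs=1e-12)

    def test_uniform_translation_equals_shift(self, toy):
        model = with_loop_trace(toy.structure, toy.loop,
                                toy.native_loop_ca + np.array([0, 0, 2.0]))
        assert loop_rmsd(model, toy.structure, toy.loop) == pytest.approx(2.0)

    def test_matches_brute_force_formula(self, toy):
        rng = np.random.default_rng(1)
        decoy = toy.native_loop_ca + rng.standard_normal((13, 3))
        model = with_loop_trace(toy.structure, toy.loop, decoy)
        expected = np.sqrt(sum(
            np.sum((decoy[k] - toy.native_loop_ca[k]) ** 2)
            for k in range(13)) / 13)
        assert loop_rmsd(model, toy.structure, toy.loop) == \
            pytest.approx(expected, abs=1e-6)

    def test_atom_set_mismatch_raises(self, toy):
        model = copy.deepcopy(toy.structure)
        i = model.chain.index_of(toy.loop.first + 1)
        model.chain.residues[i].atoms = [a for a in
                                         model.chain.residues[i].atoms
                                         if a.name == "CA"]
        with pytest.raises(ValueError):
            loop_rmsd(model, toy.structure, toy.loop, atom_mode="heavy")


class TestClustering:
    def test_single_cluster_contains_everything(self):
        rng = np.random.default_rng(0)
        ens = rng.normal(size=(15, 8, 3))
        res = cluster_models(ens, K=1, seed=0)
        assert res.cluster_sizes == [15]
        assert set(res.assignments.values()) == {0}

    def test_separable_blobs_perfectly_partitioned(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.5, (20, 13, 3))
        b = rng.normal(0, 0.5, (20, 13, 3)) + 20.0
        res = cluster_models(np.concatenate([a, b]), K=2, seed=0)
        first = {res.assignments[i] for i in range(20)}
        second = {res.assignments[i] for i in range(20, 40)}
        assert len(first) == 1 and len(second) == 1 and first != second

    def test_sizes_sum_to_ensemble(self):
        rng = np.random.default_rng(2)
        ens = rng.normal(size=(37, 5, 3))
        res = cluster_models(ens, K=6, seed=0)
        assert sum(res.cluster_sizes) == 37
        assert sorted(res.cluster_sizes, reverse=True) == res.cluster_sizes
        assert len(res.representatives) == len(res.cluster_sizes)

    def test_representative_is_a_member(self):
        rng = np.random.default_rng(3)
        ens = rng.normal(size=(20, 4, 3))
        res = cluster_models(ens, K=4, seed=0)
        for rank, rep in enumerate(res.representatives):
            assert res.assignments[rep] == rank

    def test_k_larger_than_ensemble_raises(self):
        with pytest.raises(ValueError):
            cluster_models(np.zeros((3, 2, 3)), K=5, seed=0)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        ens = rng.normal(size=(30, 6, 3))
        r1 = cluster_models(ens, K=5, seed=9)
        r2 = cluster_models(ens, K=5, seed=9)
        assert r1.assignments == r2.assignments


class TestSelection:
    def _clusters(self, reps, n):
        sizes = [n - len(reps) + 1] + [1] * (len(reps) - 1)
        assignments = {}
        for m in range(n):
            assignments[m] = reps.index(m) if m in reps else 0
        return ClusterResult(assignments, sizes, list(reps))

    def test_hand_built_ensemble_matches_enumeration(self):
        energies = [5.0, 1.0, 3.0, 2.0, 4.0]
        rmsds = {0: 2.5, 1: 4.0, 2: 0.7, 3: 3.0, 4: 1.1}
        scores = [ModelScore(i, e) for i, e in enumerate(energies)]
        clusters = self._clusters([3, 0, 4], 5)
        rep = select_models(scores, clusters, rmsds)
        # exhaustive oracle over the defined subsets
        order = sorted(range(5), key=lambda m: energies[m])
        assert rep.rmsd_le == rmsds[order[0]] == 4.0
        assert rep.rmsd_le10 == min(rmsds[m] for m in order[:10]) == 0.7
        assert rep.rmsd_best == min(rmsds.values()) == 0.7
        assert rep.rmsd_lc == rmsds[3] == 3.0
        assert rep.rmsd_lc10 == min(rmsds[m] for m in (3, 0, 4)) == 1.1
        assert rep.selected["LE"] == 1
        assert rep.selected["BEST"] == 2

    def test_subset_minimum_chain_on_random_inputs(self):
        rng = np.random.default_rng(5)
        for trial in range(20):
            n = int(rng.integers(5, 150))
            scores = [ModelScore(i, float(rng.normal())) for i in range(n)]
            rmsds = {i: float(rng.uniform(0.5, 9)) for i in range(n)}
            reps = list(rng.permutation(n)[:min(n, 17)])
            clusters = self._clusters([int(r) for r in reps], n)
            rep = select_models(scores, clusters, rmsds)
            assert rep.rmsd_best <= rep.rmsd_le100 <= rep.rmsd_le10 <= rep.rmsd_le
            assert rep.rmsd_best <= rep.rmsd_lc100 <= rep.rmsd_lc10 <= rep.rmsd_lc

    def test_energy_ties_break_to_lowest_model_id(self):
        scores = [ModelScore(i, 1.0) for i in range(4)]
        clusters = self._clusters([2], 4)
        rep = select_models(scores, clusters, {i: 1.0 for i in range(4)})
        assert rep.selected["LE"] == 0

    def test_without_reference_reports_selections_only(self):
        scores = [ModelScore(i, float(i)) for i in range(5)]
        clusters = self._clusters([4, 1], 5)
        rep = select_models(scores, clusters, None)
        assert rep.rmsd_best is None and rep.rmsd_le is None
        assert rep.selected["LE"] == 0 and rep.selected["LC"] == 4
        assert rep.candidates["LE10"] == [0, 1, 2, 3, 4]


def test_decoy_rmsds_match_generation_bookkeeping(toy):
    ensemble, true_rmsd = make_decoy_ensemble(toy.native_loop_ca, 10, 1.0,
                                              seed=2)
    for k in range(10):
        model = with_loop_trace(toy.structure, toy.loop, ensemble[k])
        assert loop_rmsd(model, toy.structure, toy.loop) == \
            pytest.approx(true_rmsd[k], abs=1e-6)
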