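import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pepdock import (ComplexModel, EnergyBreakdown, k_medoids, ligand_rmsd,
                     native_contacts, pairwise_ligand_rmsd, rank_models,
                     rmsd_report, select_random_contact, top_by_energy)
from pepdock.selection import Cluster, ClusterReport, cluster_density
from pepdock.toys import make_decoy_set

from conftest import make_line_chain


def _model_with_energy(base, scoring, cycle=0, replica=0, model_id=0):
    m = base.copy()
    m.energy = EnergyBreakdown(pair_contact=scoring)
    m.cycle = cycle
    m.replica_id = replica
    m.model_id = model_id
    return m


class TestTopByEnergy:
    def test_selects_lowest_and_sorts(self, toy, rng):
        base = toy.native_model
        energies = rng.permutation(np.arange(50.0))
        pool = [_model_with_energy(base, e, model_id=i)
                for i, e in enumerate(energies)]
        got = top_by_energy(pool, 10)
        assert [m.energy.scoring_energy for m in got] == sorted(energies)[:10]
        assert max(m.energy.scoring_energy for m in got) <= min(
            m.energy.scoring_energy for m in pool if m not in got)

    def test_clamps_to_pool_size(self, toy):
        pool = [_model_with_energy(toy.native_model, e) for e in (3.0, 1.0)]
        assert len(top_by_energy(pool, 100)) == 2

    def test_tie_break_by_cycle_then_replica(self, toy):
        pool = [_model_with_energy(toy.native_model, 1.0, cycle=c, replica=r)
                for c, r in [(5, 1), (2, 9), (2, 3)]]
        got = top_by_energy(pool, 3)
        assert [(m.cycle, m.replica_id) for m in got] == [(2, 3), (2, 9), (5, 1)]

    def test_empty_pool_is_error(self):
        with pytest.raises(ValueError):
            top_by_energy([], 10)


class TestLigandRmsd:
    def test_identity(self, toy):
        assert ligand_rmsd(toy.native_model, toy.native_model) == \
            pytest.approx(0.0, abs=1e-12)

    def test_global_rotation_removed(self, toy, rng):
        m = toy.native_model
        R = Rotation.random(random_state=rng).as_matrix()
        t = rng.uniform(-30, 30, 3)
        moved = ComplexModel(m.receptor.transformed(R, t),
                             m.peptide.transformed(R, t))
        assert ligand_rmsd(moved, m) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_translation_equals_norm(self, toy, rng):
        m = toy.native_model
        for _ in range(5):
            t = rng.uniform(-5, 5, 3)
            shifted = ComplexModel(m.receptor.copy(),
                                   m.peptide.transformed(translation=t))
            assert ligand_rmsd(shifted, m) == pytest.approx(
                np.linalg.norm(t), abs=1e-9)

    def test_symmetry_and_triangle_inequality(self, toy, rng):
        m = toy.native_model
        models = []
        for _ in range(6):
            pert = m.copy()
            pert.peptide.ca += rng.normal(scale=2.0, size=pert.peptide.ca.shape)
            pert.receptor.ca += rng.normal(scale=0.2,
                                           size=pert.receptor.ca.shape)
            models.append(pert)
        for a, b, c in itertools.permutations(models, 3):
            dab = ligand_rmsd(a, b)
            assert dab == pytest.approx(ligand_rmsd(b, a), abs=1e-6)
            assert dab <= ligand_rmsd(a, c) + ligand_rmsd(c, b) + 1e-6

    def test_size_mismatch_is_error(self, toy, small_toy):
        with pytest.raises(ValueError):
            ligand_rmsd(toy.native_model, small_toy.native_model)

    def test_batched_matrix_matches_pairwise_calls(self, toy, rng):
        m = toy.native_model
        models = []
        for _ in range(5):
            pert = m.copy()
            pert.peptide.ca += rng.normal(scale=3.0, size=pert.peptide.ca.shape)
            pert.receptor.ca += rng.normal(scale=0.3,
                                           size=pert.receptor.ca.shape)
            models.append(pert)
        D = pairwise_ligand_rmsd(models, block=2)
        for i in range(5):
            for j in range(5):
                assert D[i, j] == pytest.approx(
                    ligand_rmsd(models[i], models[j]), abs=1e-6)


def _brute_force_kmedoids(D, k):
    n = D.shape[0]
    best_cost, best_set = np.inf, None
    for medoids in itertools.combinations(range(n), k):
        cost = D[:, medoids].min(axis=1).sum()
        if cost < best_cost - 1e-12:
            best_cost, best_set = cost, set(medoids)
    return best_cost, best_set


class TestKMedoids:
    def test_line_example_matches_exhaustive(self, toy):
        # 5 points on a line, k=2: optimum found by trying all C(5,2) pairs
        x = np.array([0.0, 1.0, 2.0, 10.0, 11.0])
        D = np.abs(x[:, None] - x[None, :])
        models = list(range(5))
        rep = k_medoids(models, 2, distance_matrix=D,
                        rng=np.random.default_rng(0))
        cost_bf, _ = _brute_force_kmedoids(D, 2)
        medoids = [c.medoid_id for c in rep.clusters]
        cost = D[:, medoids].min(axis=1).sum()
        assert cost == pytest.approx(cost_bf)

    def test_k_equals_n_zero_cost(self):
        D = np.abs(np.arange(4.0)[:, None] - np.arange(4.0)[None, :])
        rep = k_medoids(list(range(4)), 4, distance_matrix=D,
                        rng=np.random.default_rng(0))
        assert sorted(c.medoid_id for c in rep.clusters) == [0, 1, 2, 3]
        for c in rep.clusters:
            assert c.member_ids == [c.medoid_id]

    def test_k_above_n_is_error(self):
        with pytest.raises(ValueError):
            k_medoids([1, 2], 3, distance_matrix=np.zeros((2, 2)))

    def test_partition_property(self, rng):
        n = 30
        pts = rng.normal(size=(n, 2))
        D = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        rep = k_medoids(list(range(n)), 4, distance_matrix=D, rng=rng)
        all_members = sorted(m for c in rep.clusters for m in c.member_ids)
        assert all_members == list(range(n))

    def test_matches_exhaustive_on_random_instances(self):
        # PAM with 5 restarts equals brute force on small instances
        rng = np.random.default_rng(2024)
        for _ in range(40):
            n = int(rng.integers(4, 9))
            k = int(rng.integers(2, 4))
            pts = rng.uniform(0, 10, size=(n, 2))
            D = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
            rep = k_medoids(list(range(n)), k, distance_matrix=D, rng=rng)
            medoids = [c.medoid_id for c in rep.clusters]
            cost = D[:, medoids].min(axis=1).sum()
            cost_bf, _ = _brute_force_kmedoids(D, k)
            assert cost == pytest.approx(cost_bf, abs=1e-9)

    def test_planted_partition_recovered(self, toy, rng):
        decoys = make_decoy_set(toy, 20, [2.0, 15.0], rng=rng)
        models = [m for m, *_ in decoys]
        labels = [t for _, t, *_ in decoys]
        rep = k_medoids(models, 2, rng=rng)
        D = pairwise_ligand_rmsd(models)
        # map clusters to labels: every cluster must be label-pure
        for c in rep.clusters:
            got = {labels[i] for i in c.member_ids}
            assert len(got) == 1


class TestClusterDensity:
    def test_hand_example(self):
        # 4 members with mean pairwise distance 2.0 -> density 2.0
        D = np.full((4, 4), 2.0)
        np.fill_diagonal(D, 0.0)
        density, degenerate = cluster_density(D)
        assert density == pytest.approx(2.0)
        assert not degenerate

    def test_inverse_linear_in_spread(self, rng):
        pts = rng.normal(size=(6, 3))
        D1 = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        d1, _ = cluster_density(D1)
        d2, _ = cluster_density(2.0 * D1)
        assert d2 == pytest.approx(d1 / 2.0)

    def test_singleton_flagged(self):
        density, degenerate = cluster_density(np.zeros((1, 1)))
        assert degenerate
        assert density == pytest.approx(1.0 / 1e-3)

    def test_medoid_spread_variant(self):
        # 3 members: distances to medoid (index 0) are 1 and 3 -> mean 2
        D = np.array([[0.0, 1.0, 3.0],
                      [1.0, 0.0, 4.0],
                      [3.0, 4.0, 0.0]])
        density, degenerate = cluster_density(D, spread="medoid",
                                              medoid_pos=0)
        assert density == pytest.approx(3.0 / 2.0)
        assert not degenerate
        # the default pairwise reading averages all three pairs
        density_pw, _ = cluster_density(D)
        assert density_pw == pytest.approx(3.0 / ((1 + 3 + 4) / 3))


class TestRankModels:
    def _report(self, sizes, densities_matrix, models):
        clusters, start = [], 0
        for s in sizes:
            clusters.append(Cluster(member_ids=list(range(start, start + s)),
                                    medoid_id=start))
            start += s
        return ClusterReport(clusters=clusters)

    def test_density_descending(self, toy):
        # three bundles with spreads giving densities 5, 9, 1
        models = [_model_with_energy(toy.native_model, 0.0, model_id=i)
                  for i in range(9)]
        D = np.zeros((9, 9))
        spreads = {0: 3 / 5.0, 3: 3 / 9.0, 6: 3.0}
        for start, spread in spreads.items():
            for i in range(start, start + 3):
                for j in range(start, start + 3):
                    if i != j:
                        D[i, j] = spread
        rep = ClusterReport(clusters=[
            Cluster(member_ids=[0, 1, 2], medoid_id=0),
            Cluster(member_ids=[3, 4, 5], medoid_id=3),
            Cluster(member_ids=[6, 7, 8], medoid_id=6)])
        rank_models(rep, models, distance_matrix=D)
        assert rep.ranking == [3, 0, 6]

    def test_tie_broken_by_size(self, toy):
        models = [_model_with_energy(toy.native_model, 0.0, model_id=i)
                  for i in range(30)]
        D = np.ones((30, 30)) * 2.0
        np.fill_diagonal(D, 0.0)
        rep = ClusterReport(clusters=[
            Cluster(member_ids=list(range(10)), medoid_id=0),
            Cluster(member_ids=list(range(10, 30)), medoid_id=10)])
        rank_models(rep, models, distance_matrix=D)
        assert rep.ranking == [10, 0]  # equal density, larger cluster first

    def test_k_in_k_out(self, toy, rng):
        decoys = make_decoy_set(toy, 40, [1.0, 4.0, 8.0, 16.0], rng=rng)
        models = [m for m, *_ in decoys]
        for i, m in enumerate(models):
            m.energy = EnergyBreakdown(pair_contact=float(i))
        rep = k_medoids(models, 10, rng=rng)
        rank_models(rep, models)
        assert len(rep.ranking) == 10


class TestNativeContacts:
    def test_distance_window(self):
        rec = make_line_chain(4, role="receptor")
        pep = make_line_chain(3).transformed(translation=[0, 60, 0])
        # put one peptide SC 4.9 A from receptor residue 2's SC
        pep.sc[1] = rec.sc[2] + np.array([0, 4.9, 0])
        got = native_contacts(rec, pep, cutoff=5.0)
        assert len(got) == 1
        assert got[0].receptor_residue == 3  # 1-based
        assert got[0].peptide_residue == 2
        pep.sc[1] = rec.sc[2] + np.array([0, 5.1, 0])
        assert native_contacts(rec, pep, cutoff=5.0) == []

    def test_toy_contacts_self_consistent(self, toy):
        got = native_contacts(toy.receptor, toy.native_peptide, cutoff=5.0)
        assert got == toy.native_contacts

    def test_bad_cutoff(self, toy):
        with pytest.raises(ValueError):
            native_contacts(toy.receptor, toy.native_peptide, cutoff=0.0)


class TestSelectRandomContact:
    def test_singleton(self):
        from pepdock.io import ContactSpec
        c = ContactSpec("A", 1, 1)
        assert select_random_contact([c]) is c

    def test_deterministic_under_seed(self, toy):
        a = select_random_contact(toy.native_contacts,
                                  np.random.default_rng(5))
        b = select_random_contact(toy.native_contacts,
                                  np.random.default_rng(5))
        assert a == b

    def test_uniformity(self, toy):
        contacts = toy.native_contacts[:4]
        rng = np.random.default_rng(1)
        counts = np.zeros(4)
        n = 10000
        for _ in range(n):
            counts[contacts.index(select_random_contact(contacts, rng))] += 1
        # 3 sigma multinomial bound around n/4
        sigma = np.sqrt(n * 0.25 * 0.75)
        assert np.all(np.abs(counts - n / 4) <= 3 * sigma)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            select_random_contact([])


class TestRmsdReport:
    def test_reference_in_final_set_gives_zero(self, toy, rng):
        decoys = make_decoy_set(toy, 12, [0.0, 3.0, 8.0], rng=rng)
        models = [m for m, *_ in decoys]
        rep = rmsd_report(models, models[:6], models[:3], [models[0]],
                          toy.native_model)
        assert rep["rmsd_10"] == pytest.approx(0.0, abs=1e-9)

    def test_nested_monotonicity(self, toy, rng):
        decoys = make_decoy_set(toy, 24, [1.0, 3.0, 6.0, 12.0], rng=rng)
        models = [m for m, *_ in decoys]
        order = rng.permutation(len(models))
        pool = [models[i] for i in order]
        rep = rmsd_report(pool, pool[:12], pool[:6], pool[:2],
                          toy.native_model)
        assert rep["rmsd_10k"] <= rep["rmsd_1k"] <= rep["rmsd_100"] \
            <= rep["rmsd_10"]

    def test_planted_tiers_give_exact_minima(self, toy, rng):
        decoys = make_decoy_set(toy, 8, [2.0, 5.0, 9.0, 14.0], rng=rng)
        models = [m for m, *_ in decoys]
        achieved = [a for _, _, a, _ in decoys]
        rep = rmsd_report(models, models[:4], models[:2], [models[1]],
                          toy.native_model)
        assert rep["rmsd_10k"] == pytest.approx(min(achieved), abs=1e-6)
        assert rep["rmsd_10"] == pytest.approx(achieved[1], abs=1e-6)

    def test_missing_reference_skips(self, toy):
        assert rmsd_report([toy.native_model], [], [], [], None) is None
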