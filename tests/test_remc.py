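import numpy as np
import pytest
from scipy import stats

from pepdock import (ComplexModel, ReplicaState, SimulationConfig,
                     attempt_exchange, metropolis_accept, propose_move,
                     scatter_peptide, surface_distance)
from pepdock.cg import BOND_MAX, BOND_MIN, LatticeConfig
from pepdock.remc import DockingSystem, MoveWeights, run_remc


class TestScatterPeptide:
    def test_within_bound_and_no_clash(self, toy, params, rng):
        from pepdock.energy import excluded_volume_energy

        for _ in range(25):
            pep = scatter_peptide(toy.receptor, toy.peptide_spec, 20.0, rng)
            assert surface_distance(pep, toy.receptor) <= 20.0
            assert excluded_volume_energy(
                ComplexModel(toy.receptor, pep)) == 0.0

    def test_deterministic_under_seed(self, toy):
        a = scatter_peptide(toy.receptor, toy.peptide_spec, 20.0,
                            np.random.default_rng(99))
        b = scatter_peptide(toy.receptor, toy.peptide_spec, 20.0,
                            np.random.default_rng(99))
        assert np.array_equal(a.ca, b.ca)

    def test_tight_bound_near_contact_or_controlled_failure(self, toy, rng):
        # a 3 A shell admits poses hugging the surface ...
        pep = scatter_peptide(toy.receptor, toy.peptide_spec, 3.0, rng,
                              max_retries=20000)
        assert surface_distance(pep, toy.receptor) <= 3.0
        # ... while a 0.5 A shell is infeasible (the excluded-volume core
        # keeps every clash-free pose at least ~1 A off the surface) and
        # must fail with a helpful error instead of hanging
        with pytest.raises(RuntimeError, match="max_dist"):
            scatter_peptide(toy.receptor, toy.peptide_spec, 0.5, rng,
                            max_retries=300)

    def test_bond_geometry_valid(self, toy, rng):
        pep = scatter_peptide(toy.receptor, toy.peptide_spec, 20.0, rng)
        d = np.linalg.norm(np.diff(pep.ca, axis=0), axis=1)
        assert np.all((d >= BOND_MIN) & (d <= BOND_MAX))

    def test_empty_receptor_is_error(self, toy, rng):
        import pepdock.cg as cg

        empty = cg.CGChain([], [], np.empty((0, 3)), np.empty((0, 3)),
                           np.empty((0, 3)))
        with pytest.raises(ValueError):
            scatter_peptide(empty, toy.peptide_spec, 20.0, rng)


def _state(toy, seed=0, temperature=1.0):
    model = ComplexModel(toy.receptor.copy(), toy.native_peptide.copy())
    return ReplicaState(model=model, temperature=temperature, replica_id=0,
                        rng_stream=np.random.default_rng(seed))


class TestProposeMove:
    def test_locality(self, toy):
        # every move changes at most the targeted chain
        st = _state(toy)
        cfg = SimulationConfig()
        rng = np.random.default_rng(3)
        for _ in range(200):
            cand, groups, name = propose_move(st, rng, cfg)
            if cand is None:
                continue
            if name == "receptor":
                assert np.array_equal(cand.peptide.ca, st.model.peptide.ca)
                changed = np.any(cand.receptor.ca != st.model.receptor.ca,
                                 axis=1)
                assert changed.sum() <= 1
            else:
                assert np.array_equal(cand.receptor.ca, st.model.receptor.ca)

    def test_move_type_frequencies_match_weights(self, toy):
        st = _state(toy)
        weights = MoveWeights()
        cfg = SimulationConfig(move_weights=weights)
        rng = np.random.default_rng(8)
        names, w = weights.as_arrays()
        counts = dict.fromkeys(names, 0)
        n = 10000
        for _ in range(n):
            _, _, name = propose_move(st, rng, cfg)
            counts[name] += 1
        for name, p in zip(names, w):
            sigma = np.sqrt(n * p * (1 - p))
            assert abs(counts[name] - n * p) <= 3 * sigma, name

    def test_lattice_respected(self, toy):
        st = _state(toy)
        cfg = SimulationConfig()
        lattice = LatticeConfig()
        rng = np.random.default_rng(4)
        for _ in range(100):
            cand, _, _ = propose_move(st, rng, cfg, lattice)
            if cand is None:
                continue
            for ca in (cand.peptide.ca, cand.receptor.ca):
                assert np.allclose(ca, lattice.spacing
                                   * np.round(ca / lattice.spacing),
                                   atol=1e-9)

    def test_bond_limits_never_violated(self, toy):
        st = _state(toy)
        cfg = SimulationConfig()
        rng = np.random.default_rng(5)
        for _ in range(300):
            cand, _, _ = propose_move(st, rng, cfg)
            if cand is None:
                continue
            for ca in (cand.peptide.ca, cand.receptor.ca):
                d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
                assert np.all((d >= BOND_MIN) & (d <= BOND_MAX))


class TestMetropolis:
    def test_downhill_always_accepted(self, rng):
        assert all(metropolis_accept(-1.0, t, rng) for t in (0.1, 1.0, 10.0))

    def test_zero_temperature_limit(self, rng):
        assert not metropolis_accept(1.0, 1e-12, rng)

    def test_acceptance_rate_at_ln2(self):
        # dE = T ln 2 gives acceptance probability exactly 1/2
        rng = np.random.default_rng(2)
        T = 1.3
        n = 100_000
        acc = sum(metropolis_accept(T * np.log(2.0), T, rng)
                  for _ in range(n))
        assert acc / n == pytest.approx(0.5, abs=0.005)

    def test_invalid_temperature(self, rng):
        with pytest.raises(ValueError):
            metropolis_accept(1.0, 0.0, rng)


def _harmonic_states(e_a, e_b, t_a=1.0, t_b=2.0):
    a = ReplicaState(model=None, temperature=t_a, replica_id=0,
                     rng_stream=None, ladder_index=0, energy=e_a)
    b = ReplicaState(model=None, temperature=t_b, replica_id=1,
                     rng_stream=None, ladder_index=1, energy=e_b)
    return a, b


class TestExchange:
    def test_equal_energy_always_accepted(self, rng):
        a, b = _harmonic_states(3.0, 3.0)
        assert attempt_exchange(a, b, rng)
        assert (a.temperature, b.temperature) == (2.0, 1.0)

    def test_equal_temperature_always_accepted(self, rng):
        a, b = _harmonic_states(1.0, 9.0, t_a=1.5, t_b=1.5)
        assert attempt_exchange(a, b, rng)

    def test_non_adjacent_is_error(self, rng):
        a, b = _harmonic_states(1.0, 2.0)
        b.ladder_index = 3
        with pytest.raises(ValueError):
            attempt_exchange(a, b, rng)

    def test_identities_preserved_on_swap(self, rng):
        a, b = _harmonic_states(3.0, 3.0)
        attempt_exchange(a, b, rng)
        assert (a.replica_id, b.replica_id) == (0, 1)

    def test_remc_matches_single_temperature_sampling(self):
        """Two-replica REMC on a 1-D harmonic well reproduces the
        per-temperature energy distributions of plain Metropolis runs
        (Kolmogorov-Smirnov, p > 0.01)."""
        temps = (1.0, 2.0)
        n_sweeps, thin, burn = 12000, 4, 2000

        def single_run(T, seed):
            rng = np.random.default_rng(seed)
            x, e = 0.0, 0.0
            out = []
            for i in range(n_sweeps):
                xn = x + rng.normal(scale=1.0)
                en = xn * xn
                if metropolis_accept(en - e, T, rng):
                    x, e = xn, en
                if i >= burn and i % thin == 0:
                    out.append(e)
            return np.asarray(out)

        def remc_run(seed):
            rng = np.random.default_rng(seed)
            ex_rng = np.random.default_rng(seed + 1)
            states = [ReplicaState(model=[0.0], temperature=t, replica_id=i,
                                   rng_stream=np.random.default_rng(seed + 2 + i),
                                   ladder_index=i, energy=0.0)
                      for i, t in enumerate(temps)]
            samples = {t: [] for t in temps}
            for i in range(n_sweeps):
                for st in states:
                    xn = st.model[0] + st.rng_stream.normal(scale=1.0)
                    en = xn * xn
                    if metropolis_accept(en - st.energy, st.temperature,
                                         st.rng_stream):
                        st.model = [xn]
                        st.energy = en
                if i % 10 == 0:
                    attempt_exchange(states[0], states[1], ex_rng)
                    states.sort(key=lambda s: s.ladder_index)
                if i >= burn and i % thin == 0:
                    for st in states:
                        samples[st.temperature].append(st.energy)
            return {t: np.asarray(v) for t, v in samples.items()}

        remc = remc_run(1000)
        for j, T in enumerate(temps):
            ref = single_run(T, 2000 + j)
            ks = stats.ks_2samp(remc[T], ref)
            assert ks.pvalue > 0.01, (T, ks)


class TestRunRemc:
    def test_pool_size_and_finiteness(self, small_toy):
        system = DockingSystem(receptor=small_toy.receptor,
                               peptide_spec=small_toy.peptide_spec)
        cfg = SimulationConfig(n_replicas=3, n_cycles=20,
                               snapshots_per_replica=20, exchange_period=5,
                               seed=1)
        traj = run_remc(system, (), cfg)
        assert len(traj) == 3 * 20
        assert np.all(np.isfinite(traj.scoring_energies()))

    def test_zero_cycles_returns_initial_states(self, small_toy):
        system = DockingSystem(receptor=small_toy.receptor,
                               peptide_spec=small_toy.peptide_spec)
        cfg = SimulationConfig(n_replicas=2, n_cycles=0,
                               snapshots_per_replica=5, seed=2)
        traj = run_remc(system, (), cfg)
        assert len(traj) == 10
        assert all(s.cycle == 0 for s in traj.snapshots)

    def test_bitwise_reproducible(self, small_toy):
        system = DockingSystem(receptor=small_toy.receptor,
                               peptide_spec=small_toy.peptide_spec)
        cfg = SimulationConfig(n_replicas=3, n_cycles=15,
                               snapshots_per_replica=10, exchange_period=5,
                               seed=7)
        e1 = run_remc(system, (), cfg).scoring_energies()
        e2 = run_remc(system, (), cfg).scoring_energies()
        assert np.array_equal(e1, e2)

    def test_geometric_ladder(self):
        cfg = SimulationConfig(n_replicas=4, t_min=1.0, t_max=8.0)
        assert np.allclose(cfg.temperature_ladder(), [1.0, 2.0, 4.0, 8.0])

    def test_fixed_point_variance_in_harmonic_well(self):
        """Detailed-balance smoke test: Metropolis sampling of a single
        coordinate in a harmonic well reproduces Var(x) = T/2 (for
        E = x^2, i.e. k = 2) within 5%."""
        T = 1.5
        rng = np.random.default_rng(42)
        x, e = 0.0, 0.0
        xs = []
        for i in range(120_000):
            xn = x + rng.normal(scale=1.2)
            en = xn * xn
            if metropolis_accept(en - e, T, rng):
                x, e = xn, en
            if i >= 5000 and i % 3 == 0:
                xs.append(x)
        var = np.var(xs)
        assert var == pytest.approx(T / 2.0, rel=0.05)
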