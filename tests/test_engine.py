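"""Index function, mass rotation, master equation, reset, networks."""

import numpy as np
import pytest
from scipy import sparse

import popmesh as pm
from popmesh.engine import (
    ConnectionSpec,
    IndexMap,
    MassState,
    Population,
    PopulationNetwork,
    firing_rate,
)
from popmesh.mesh import MappingTable

from conftest import population_of


class TestIndexFunction:
    def test_stationary_cells_never_rotate(self):
        im = IndexMap(n_stationary=3, n_cell=[4, 7])
        for k in (0, 1, 5, 100):
            assert im.index(0, 2, k) == 2

    def test_direct_evaluation(self):
        im = IndexMap(n_stationary=1, n_cell=[4])
        assert im.index(1, 2, 0) == 3
        # non-negative modulo: 1 + ((2 - 3) mod 4) = 4
        assert im.index(1, 2, 3) == 4

    def test_invalid_coordinates(self):
        im = IndexMap(n_stationary=1, n_cell=[4])
        with pytest.raises(IndexError):
            im.index(1, 4, 0)
        with pytest.raises(IndexError):
            im.index(2, 0, 0)

    def test_against_mass_copying_oracle(self):
        """Index addressing agrees exactly with an explicit rotation that
        physically copies mass arrays, over random strip layouts."""
        rng = np.random.default_rng(0)
        checked = 0
        while checked < 10_000:
            n_stat = int(rng.integers(0, 3))
            sizes = rng.integers(1, 9, size=rng.integers(1, 4))
            im = IndexMap(n_stationary=n_stat, n_cell=sizes)
            n = im.n_total
            mass = rng.random(n)
            k = int(rng.integers(0, 25))
            # oracle: roll each strip's slice forward k times
            oracle = mass.copy()
            off = n_stat
            for sz in sizes:
                oracle[off : off + sz] = np.roll(mass[off : off + sz], k)
                off += sz
            # engine: reading static (i, j) at step k from the unrolled
            # array must equal reading (i, j) at step 0 from the oracle
            for i in range(len(sizes)):
                for j in range(sizes[i]):
                    assert oracle[im.index(i + 1, j, 0)] == (
                        mass[im.index(i + 1, j, k)]
                    )
                    checked += 1

    def test_perm_matches_index(self):
        im = IndexMap(n_stationary=2, n_cell=[3, 5])
        for k in (0, 2, 9):
            perm = im.perm(k)
            flat = 0
            for j in range(2):
                assert perm[flat] == im.index(0, j, k)
                flat += 1
            for i, sz in enumerate((3, 5), start=1):
                for j in range(sz):
                    assert perm[flat] == im.index(i, j, k)
                    flat += 1


class TestStepDeterministic:
    def test_stationary_mass_unchanged(self, toy_fx):
        pop = population_of(toy_fx)
        st = pop.point_mass_state((0, 0))
        before = st.mass.copy()
        pop.step_deterministic(st)
        assert st.k == 1
        assert np.array_equal(st.mass, before)

    def test_transfer_timing_single_strip(self):
        """Mass in cell j of an n-cell strip reaches the reversal target
        after exactly n - j steps (hand-rotated with n=3, j=2)."""
        from popmesh.fixtures import _rect
        from popmesh.mesh import Mesh

        mesh = Mesh(dt=1e-3)
        mesh.add_stationary_cell(
            np.array([[-1.0, 0], [0.0, 0], [0.0, 1], [-1.0, 1.0]])
        )
        mesh.add_strip([_rect(k, k + 1, 0, 1, 1, k) for k in range(3)])
        table = MappingTable("reversal", [((1, 0), (0, 0), 1.0)])
        pop = Population(mesh, table)
        st = pop.point_mass_state((1, 2))
        pop.step_deterministic(st)
        assert st.mass[0] == 1.0  # last cell wraps to address 0 immediately
        st2 = pop.point_mass_state((1, 1))
        pop.step_deterministic(st2)
        assert st2.mass[0] == 0.0
        pop.step_deterministic(st2)
        assert st2.mass[0] == 1.0  # j=1 arrives after 2 steps

    def test_rotation_is_a_permutation(self, toy_fx):
        pop = population_of(toy_fx)
        st = pop.zero_state()
        rng = np.random.default_rng(1)
        st.mass[:] = rng.random(len(st.mass))
        st.mass /= st.mass.sum()
        sorted_before = np.sort(st.mass)
        # suppress the reversal transfer to observe the pure rotation
        pop._rev = None
        pop.step_deterministic(st)
        assert np.array_equal(np.sort(st.mass), sorted_before)

    def test_conservation(self, toy_fx):
        pop = population_of(toy_fx)
        st = pop.zero_state()
        rng = np.random.default_rng(2)
        st.mass[:] = rng.random(len(st.mass))
        st.mass /= st.mass.sum()
        for _ in range(10):
            pop.step_deterministic(st)
            assert st.mass.sum() == pytest.approx(1.0, abs=1e-15)


class TestMasterStep:
    def _two_cell_pop(self):
        from popmesh.fixtures import _rect
        from popmesh.mesh import Mesh

        mesh = Mesh(dt=1e-3)
        mesh.add_stationary_cell(np.array([[0, 0], [1, 0], [1, 1], [0, 1.0]]))
        mesh.add_stationary_cell(np.array([[1, 0], [2, 0], [2, 1], [1, 1.0]]))
        return Population(mesh, None)

    def _matrix(self, counts, n_point):
        from popmesh.transition import TransitionMatrix

        return TransitionMatrix(
            mesh_id="toy", jump_label="x", n_point=n_point, seed=0,
            counts=sparse.csr_matrix(np.asarray(counts)),
            coords=[(0, 0), (0, 1)],
        )

    def test_single_euler_step_arithmetic(self):
        pop = self._two_cell_pop()
        tm = self._matrix([[0, 10], [0, 10]], 10)  # cell 0 -> cell 1
        st = pop.zero_state()
        st.mass[0] = 1.0
        pop.master_step(st, [(tm, 100.0)], dt=1e-3, n_euler=1)
        assert np.allclose(st.mass, [0.9, 0.1])

    def test_zero_rate_is_identity(self, lif_fx):
        pop = population_of(lif_fx)
        st = pop.point_mass_state((0, 0))
        before = st.mass.copy()
        pop.master_step(st, [(lif_fx["matrix"], 0.0)], dt=1e-4)
        assert np.array_equal(st.mass, before)

    def test_stability_guard(self):
        pop = self._two_cell_pop()
        tm = self._matrix([[0, 10], [0, 10]], 10)
        st = pop.zero_state()
        st.mass[0] = 1.0
        with pytest.raises(ValueError, match="n_euler"):
            pop.master_step(st, [(tm, 5000.0)], dt=1e-3, n_euler=1)

    def test_conservation_random_row_stochastic(self):
        """Mass is conserved under arbitrary row-stochastic matrices."""
        rng = np.random.default_rng(3)
        from popmesh.fixtures import _rect
        from popmesh.mesh import Mesh
        from popmesh.transition import TransitionMatrix

        n = 12
        mesh = Mesh(dt=1e-3)
        for j in range(n):
            mesh.add_stationary_cell(
                np.array([[j, 0], [j + 1, 0], [j + 1, 1], [j, 1.0]])
            )
        pop = Population(mesh, None)
        for trial in range(5):
            counts = rng.integers(0, 50, size=(n, n))
            counts[counts.sum(axis=1) == 0, 0] = 1
            npoint = counts.sum(axis=1)
            # normalise rows to a common denominator
            lcm = int(np.lcm.reduce(npoint))
            counts = counts * (lcm // npoint)[:, None]
            tm = TransitionMatrix(
                "toy", "x", lcm, 0, sparse.csr_matrix(counts),
                [(0, j) for j in range(n)],
            )
            st = pop.zero_state()
            st.mass[:] = rng.random(n)
            st.mass /= st.mass.sum()
            pop.master_step(st, [(tm, 400.0)], dt=1e-3, n_euler=10)
            assert st.mass.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(st.mass >= -1e-15)


class TestReset:
    def _strip_pop(self, tau_ref=0.0):
        from popmesh.fixtures import _rect
        from popmesh.mesh import Mesh

        mesh = Mesh(dt=1e-3)
        mesh.add_stationary_cell(np.array([[-1, 0], [0, 0], [0, 1], [-1, 1.0]]))
        mesh.add_strip([_rect(k, k + 1, 0, 1, 1, k) for k in range(3)])
        reset = MappingTable("reset", [((1, 2), (0, 0), 1.0)])
        rev = MappingTable("reversal", [((1, 0), (0, 0), 1.0)])
        return Population(mesh, rev, reset, tau_ref=tau_ref)

    def test_no_mass_at_threshold(self):
        pop = self._strip_pop()
        st = pop.point_mass_state((1, 0))
        spiked = pop.apply_reset(st, dt=1e-3)
        assert spiked == 0.0

    def test_fraction_one_transfer(self):
        pop = self._strip_pop()
        st = pop.point_mass_state((1, 2))
        spiked = pop.apply_reset(st, dt=1e-3)
        assert spiked == pytest.approx(1.0)
        assert st.mass[0] == pytest.approx(1.0)

    def test_refractory_queue_timing(self):
        """With tau_ref = 2 dt, spiked mass reappears exactly 2 steps later;
        the total of live plus queued mass is conserved throughout."""
        pop = self._strip_pop(tau_ref=2e-3)
        st = pop.point_mass_state((1, 2))
        spiked = pop.apply_reset(st, dt=1e-3)
        assert spiked == pytest.approx(1.0)
        assert st.mass.sum() == pytest.approx(0.0)
        assert st.total_mass == pytest.approx(1.0)
        # event-list oracle: release at k = 0 + round(tau_ref/dt) = 2
        for step in (1, 2):
            pop.step_deterministic(st)
            pop.apply_reset(st, dt=1e-3)
            assert st.total_mass == pytest.approx(1.0, abs=1e-12)
        assert st.queue == []
        assert st.mass[0] == pytest.approx(1.0)  # reappeared at the target


def test_firing_rate_definition():
    assert firing_rate(0.001, 1e-3) == pytest.approx(1.0)
    assert firing_rate(0.0, 1e-3) == 0.0
    with pytest.raises(ValueError):
        firing_rate(0.1, 0.0)


class TestRun:
    def test_zero_input_stationary(self, toy_fx):
        pop = population_of(toy_fx, "p")
        st = pop.point_mass_state((0, 0))
        res = pm.run(pop, [], 0.01, state=st)
        assert np.all(res.rate("p") == 0.0)
        assert st.mass[0] == 1.0

    def test_lif_benchmark_reaches_steady_state(self, lif_fx):
        from popmesh.observables import steady_state_reached

        pop = population_of(lif_fx, "lif")
        st = pop.point_mass_state((0, 0))
        res = pm.run(pop, [(lif_fx["matrix"], 800.0)], 0.5, state=st)
        r = res.rate("lif")
        assert steady_state_reached(r, res.dt, window=0.05, cv_tol=1e-2)
        assert 5.0 < r[-100:].mean() < 20.0

    def test_delayed_connection_impulse(self):
        """Population A's output reaches B only after the transmission
        delay (two stationary cells, jumps move mass into a firing cell)."""
        from popmesh.mesh import Mesh
        from popmesh.transition import TransitionMatrix

        mesh = Mesh(dt=1e-3)
        mesh.add_stationary_cell(np.array([[0, 0], [1, 0], [1, 1], [0, 1.0]]))
        mesh.add_stationary_cell(np.array([[1, 0], [2, 0], [2, 1], [1, 1.0]]))
        tm = TransitionMatrix(
            "toy", "x", 10, 0,
            sparse.csr_matrix(np.array([[0, 10], [0, 10]])),
            [(0, 0), (0, 1)],
        )
        reset = MappingTable("reset", [((0, 1), (0, 0), 1.0)])
        a = Population(mesh, None, reset, name="A")
        b = Population(mesh, None, reset, name="B")
        delay = 5e-3
        net = PopulationNetwork(
            [a, b],
            [
                ConnectionSpec("ext:0", "A", tm, rate_fn=500.0),
                ConnectionSpec("A", "B", tm, n_con=10, tau_delay=delay),
            ],
        )
        states = {
            "A": a.point_mass_state((0, 0)),
            "B": b.point_mass_state((0, 0)),
        }
        res = net.run(0.02, states=states)
        ra, rb = res.rates["A"], res.rates["B"]
        d_steps = int(np.ceil(delay / mesh.dt))
        assert ra[0] > 0                       # A fires from the first step
        assert np.all(rb[:d_steps] == 0.0)     # B silent during the delay
        assert rb[d_steps] > 0.0

    def test_mismatched_dt_rejected(self, toy_fx, lif_fx):
        a = population_of(toy_fx, "A")
        b = population_of(lif_fx, "B")
        net = PopulationNetwork([a, b], [])
        with pytest.raises(ValueError, match="time step"):
            net.run(0.01)
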