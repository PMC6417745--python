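"""Time stepping of the population density on a state-space mesh.

Probability mass lives in a flat array of length N_cells.  Deterministic
motion is implemented *without copying mass*: a time-dependent index
function maps grid coordinates (i, j) at simulation step k to array slots,

    I(0, j, k) = j
    I(i, j, k) = c_cell(i-1) + (j - k) mod n_cell(i),   i >= 1,

so incrementing k rotates mass forward through every strip at once.  Mass
reaching the end of a strip — addressed by cell (i, 0) after the rotation —
is transferred by the reversal mapping.  Synaptic input is the forward-Euler
solution of the Poisson master equation with Monte-Carlo transition
matrices; threshold-straddling cells are drained through the reset mapping
immediately afterwards, before the next index update.  The per-step order
is therefore: rotate + reversal, master equation, reset, record rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable

import numpy as np

from .mesh import MappingTable, Mesh
from .transition import TransitionMatrix

__all__ = [
    "IndexMap",
    "MassState",
    "Population",
    "ConnectionSpec",
    "PopulationNetwork",
    "RunResult",
    "firing_rate",
    "run",
]

MASS_TOL = 1e-8  # abort threshold on global mass balance


class MassBalanceError(RuntimeError):
    """Total (live + queued) probability mass drifted beyond tolerance."""


@dataclass
class IndexMap:
    """Cumulative cell counts implementing the time-dependent index function."""

    n_stationary: int
    n_cell: np.ndarray  # cells per strip, strips 1..N
    offsets: np.ndarray = dc_field(init=False)  # flat offset per strip

    def __post_init__(self):
        self.n_cell = np.asarray(self.n_cell, dtype=np.int64)
        self.offsets = self.n_stationary + np.concatenate(
            [[0], np.cumsum(self.n_cell[:-1])]
        ).astype(np.int64)

    @classmethod
    def from_mesh(cls, mesh: Mesh) -> "IndexMap":
        return cls(
            n_stationary=len(mesh.stationary_cells),
            n_cell=np.array([len(s) for s in mesh.strips], dtype=np.int64),
        )

    @property
    def n_total(self) -> int:
        return int(self.n_stationary + self.n_cell.sum())

    def index(self, i: int, j: int, k: int) -> int:
        """Array slot of grid cell (i, j) at simulation step k."""
        if i == 0:
            if not 0 <= j < self.n_stationary:
                raise IndexError(f"stationary cell {j} out of range")
            return j
        if not 1 <= i <= len(self.n_cell) or not 0 <= j < self.n_cell[i - 1]:
            raise IndexError(f"cell ({i}, {j}) not in mesh")
        n = int(self.n_cell[i - 1])
        return int(self.offsets[i - 1]) + (j - k) % n

    def perm(self, k: int) -> np.ndarray:
        """Slot of every cell in flat static order at step k (vectorised)."""
        out = np.empty(self.n_total, dtype=np.int64)
        out[: self.n_stationary] = np.arange(self.n_stationary)
        for s, n in enumerate(self.n_cell):
            off = self.offsets[s]
            out[off : off + n] = off + (np.arange(n) - k) % n
        return out


@dataclass
class MassState:
    """Probability mass array (slot-indexed), rotation counter, refractory queue."""

    mass: np.ndarray
    k: int = 0
    queue: list[tuple[int, float, int]] = dc_field(default_factory=list)
    # queue entries: (release step, mass, target flat static id)

    @property
    def queued_mass(self) -> float:
        return sum(m for _, m, _ in self.queue)

    @property
    def total_mass(self) -> float:
        return float(self.mass.sum()) + self.queued_mass

    def copy(self) -> "MassState":
        return MassState(self.mass.copy(), self.k, list(self.queue))


def firing_rate(spiked_mass: float, dt: float) -> float:
    """Population rate in Hz: fraction of mass through threshold per unit time."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    return spiked_mass / dt


class Population:
    """A mesh plus its mappings, ready for time stepping."""

    def __init__(
        self,
        mesh: Mesh,
        reversal: MappingTable | None = None,
        reset: MappingTable | None = None,
        tau_ref: float = 0.0,
        name: str = "pop",
    ):
        self.mesh = mesh
        self.name = name
        self.index_map = IndexMap.from_mesh(mesh)
        self.tau_ref = float(tau_ref)
        if reversal is not None:
            reversal.validate(mesh)
        if reset is not None:
            reset.validate(mesh)
        self.reversal = reversal
        self.reset = reset
        self._rev = self._compile(reversal)
        self._res = self._compile(reset)

    def _compile(self, table: MappingTable | None):
        if table is None or not table.entries:
            return None
        src = np.array(
            [self.mesh.flat_index(*s) for s, _, _ in table.entries], dtype=np.int64
        )
        tgt = np.array(
            [self.mesh.flat_index(*t) for _, t, _ in table.entries], dtype=np.int64
        )
        frac = np.array([f for _, _, f in table.entries])
        usrc = np.unique(src)
        return usrc, src, tgt, frac

    def zero_state(self) -> MassState:
        return MassState(np.zeros(self.index_map.n_total))

    def point_mass_state(self, coords: tuple[int, int]) -> MassState:
        s = self.zero_state()
        s.mass[self.mesh.flat_index(*coords)] = 1.0
        return s

    def mass_static(self, state: MassState) -> np.ndarray:
        """Mass re-addressed to flat static (strip, cell) order."""
        return state.mass[self.index_map.perm(state.k)]

    # -- the three phases of one time step ---------------------------------

    def step_deterministic(self, state: MassState) -> None:
        """Rotate mass one cell forward (k += 1) and apply the reversal mapping."""
        state.k += 1
        if self._rev is None:
            return
        usrc, src, tgt, frac = self._rev
        perm = self.index_map.perm(state.k)
        amounts = state.mass[perm[src]] * frac
        state.mass[perm[usrc]] = 0.0
        np.add.at(state.mass, perm[tgt], amounts)

    def master_step(
        self,
        state: MassState,
        matrices: list[tuple[TransitionMatrix, float]],
        dt: float,
        n_euler: int = 10,
        generators=None,
    ) -> None:
        """n_euler forward-Euler substeps of the summed Poisson master equation."""
        rates = np.array([nu for _, nu in matrices])
        if (rates < 0).any():
            raise ValueError("input rates must be nonnegative")
        nu_tot = float(rates.sum())
        if nu_tot == 0.0:
            return
        if nu_tot * dt / n_euler >= 1.0:
            raise ValueError(
                f"unstable Euler step: nu*dt/n_euler = {nu_tot * dt / n_euler:.3g}"
                " >= 1; raise n_euler"
            )
        if generators is None:
            generators = [tm.generator_t() for tm, _ in matrices]
        perm = self.index_map.perm(state.k)
        m = state.mass[perm]
        step = dt / n_euler
        for _ in range(n_euler):
            dm = np.zeros_like(m)
            for g, nu in zip(generators, rates):
                if nu > 0:
                    dm += nu * (g @ m)
            m += step * dm
        state.mass[perm] = m

    def apply_reset(self, state: MassState, dt: float) -> float:
        """Drain threshold cells through the reset mapping; return spiked mass.

        With a refractory period the mass is queued and reappears at its
        reset targets ``round(tau_ref/dt)`` steps later.
        """
        # release mass whose refractory period has expired
        if state.queue:
            perm = self.index_map.perm(state.k)
            still: list[tuple[int, float, int]] = []
            for release_k, m, t in state.queue:
                if release_k <= state.k:
                    state.mass[perm[t]] += m
                else:
                    still.append((release_k, m, t))
            state.queue = still
        if self._res is None:
            return 0.0
        usrc, src, tgt, frac = self._res
        perm = self.index_map.perm(state.k)
        src_mass = state.mass[perm[src]]
        spiked = float(state.mass[perm[usrc]].sum())
        if spiked == 0.0:
            return 0.0
        amounts = src_mass * frac
        state.mass[perm[usrc]] = 0.0
        if self.tau_ref > 0.0:
            release = state.k + int(round(self.tau_ref / dt))
            for m, t in zip(amounts, tgt):
                if m > 0:
                    state.queue.append((release, float(m), int(t)))
        else:
            np.add.at(state.mass, perm[tgt], amounts)
        return spiked


@dataclass
class ConnectionSpec:
    """A delayed connection: (N_con, efficacy-specific matrix, tau_delay)."""

    source: str  # population name, or 'ext:<label>' for an external drive
    target: str
    matrix: TransitionMatrix
    n_con: int = 1
    tau_delay: float = 0.0
    rate_fn: Callable[[float], float] | float | None = None  # external only

    def __post_init__(self):
        if self.n_con < 1:
            raise ValueError("N_con must be >= 1")
        if self.tau_delay < 0:
            raise ValueError("tau_delay must be >= 0")


@dataclass
class RunResult:
    """Time series produced by a simulation run."""

    times: np.ndarray
    rates: dict[str, np.ndarray]
    snapshots: dict[str, dict[int, np.ndarray]]
    dt: float

    def rate(self, name: str | None = None) -> np.ndarray:
        if name is None:
            name = next(iter(self.rates))
        return self.rates[name]

    def to_frame(self):
        import pandas as pd

        rows = []
        for name, r in self.rates.items():
            rows.append(
                pd.DataFrame({"t": self.times, "population": name, "rate": r})
            )
        return pd.concat(rows, ignore_index=True)


def _euler_substeps(nu_tot: float, dt: float, n_euler: int) -> int:
    """Auto-raise n_euler so that nu*dt/n stays below 0.1."""
    if nu_tot <= 0:
        return n_euler
    return max(n_euler, int(np.ceil(nu_tot * dt / 0.1)))


class PopulationNetwork:
    """Populations wired by delayed connections exchanging firing rates."""

    def __init__(self, populations: list[Population], connections: list[ConnectionSpec]):
        self.populations = {p.name: p for p in populations}
        if len(self.populations) != len(populations):
            raise ValueError("population names must be unique")
        self.connections = connections
        for c in connections:
            if c.target not in self.populations:
                raise ValueError(f"unknown target population {c.target!r}")
            if not c.source.startswith("ext") and c.source not in self.populations:
                raise ValueError(f"unknown source population {c.source!r}")

    def run(
        self,
        t_end: float,
        n_euler: int = 10,
        states: dict[str, MassState] | None = None,
        snapshot_stride: int | None = None,
        check_mass: bool = True,
    ) -> RunResult:
        pops = self.populations
        dt = next(iter(pops.values())).mesh.dt
        for p in pops.values():
            if abs(p.mesh.dt - dt) > 1e-15:
                raise ValueError("all populations must share the grid time step")
        n_steps = int(round(t_end / dt))
        if states is None:
            states = {}
        for name, p in pops.items():
            states.setdefault(name, p.point_mass_state(_default_start(p)))
        history: dict[str, list[float]] = {n: [] for n in pops}
        rates_out: dict[str, list[float]] = {n: [] for n in pops}
        snaps: dict[str, dict[int, np.ndarray]] = {n: {} for n in pops}
        gens = {id(c): c.matrix.generator_t() for c in self.connections}
        m0 = {n: states[n].total_mass for n in pops}
        for step in range(n_steps):
            t = step * dt
            # per-connection presynaptic rates: externals sampled now,
            # internal rates read from history through the delay buffer
            per_pop: dict[str, list[tuple[TransitionMatrix, float, object]]] = {
                n: [] for n in pops
            }
            for c in self.connections:
                if c.source.startswith("ext"):
                    nu = c.rate_fn(t) if callable(c.rate_fn) else float(c.rate_fn)
                else:
                    d = max(1, int(np.ceil(c.tau_delay / dt)))
                    idx = step - d
                    nu = history[c.source][idx] if idx >= 0 else 0.0
                    nu *= c.n_con
                per_pop[c.target].append((c.matrix, nu, gens[id(c)]))
            for name, p in pops.items():
                st = states[name]
                p.step_deterministic(st)
                mats = [(m, nu) for m, nu, _ in per_pop[name]]
                if mats:
                    nu_tot = sum(nu for _, nu in mats)
                    p.master_step(
                        st, mats, dt,
                        n_euler=_euler_substeps(nu_tot, dt, n_euler),
                        generators=[g for _, _, g in per_pop[name]],
                    )
                spiked = p.apply_reset(st, dt)
                r = firing_rate(spiked, dt)
                history[name].append(r)
                rates_out[name].append(r)
                if snapshot_stride and step % snapshot_stride == 0:
                    snaps[name][step] = p.mass_static(st)
                if check_mass and abs(st.total_mass - m0[name]) > MASS_TOL:
                    raise MassBalanceError(
                        f"population {name!r} at step {step}: total mass "
                        f"{st.total_mass:.12f} != {m0[name]:.12f}"
                    )
        times = (np.arange(n_steps) + 1) * dt
        return RunResult(
            times=times,
            rates={n: np.array(v) for n, v in rates_out.items()},
            snapshots=snaps,
            dt=dt,
        )


def _default_start(p: Population) -> tuple[int, int]:
    if p.mesh.stationary_cells:
        return (0, 0)
    return (1, 0)


def run(
    population: Population,
    inputs: list[tuple[TransitionMatrix, float | Callable[[float], float]]],
    t_end: float,
    state: MassState | None = None,
    n_euler: int = 10,
    snapshot_stride: int | None = None,
    check_mass: bool = True,
) -> RunResult:
    """Run a single population under external Poisson drive.

    ``inputs`` pairs each transition matrix with a rate in Hz (a constant or
    a function of time, sampled once per step).  Steps follow the canonical
    order: rotate + reversal, master equation, reset, record rate.
    """
    conns = [
        ConnectionSpec(
            source=f"ext:{i}", target=population.name, matrix=tm, rate_fn=nu
        )
        for i, (tm, nu) in enumerate(inputs)
    ]
    net = PopulationNetwork([population], conns)
    st = {population.name: state} if state is not None else None
    return net.run(
        t_end, n_euler=n_euler, states=st, snapshot_stride=snapshot_stride,
        check_mass=check_mass,
    )
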