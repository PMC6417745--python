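"""Direct Monte-Carlo simulation of spiking neurons under Poisson input.

The validation oracle for the density method: N independent neurons, each
integrating the deterministic field between Poisson-distributed input
spikes that displace the state instantaneously by the synaptic efficacy.
Threshold, reset, adaptation increments and refractory periods follow the
neuron model.  The population rate is spikes per time bin divided by
(N x bin width).

Two integration paths are used.  Models with a closed-form deterministic
propagator (LIF, QIF, the TM synapse) are simulated *exactly* event by
event: inter-arrival times are exponential draws and the flow between
arrivals is evaluated analytically, including analytic threshold-crossing
times where drift alone can reach threshold.  Models without a closed form
(conductance, AdExp, FHN) use fixed sub-steps of ``dt_mc`` with a classical
RK4 update and Poisson-distributed arrival counts per step; the jump-time
discretisation bias is O(dt_mc), and ``dt_mc`` is required to be at most a
fifth of the mesh time step.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .models import NeuronModel

__all__ = ["MCResult", "simulate", "binned_rate", "steady_rate"]


@dataclass
class MCResult:
    """Spike and state output of a direct simulation."""

    model: str
    n_neurons: int
    t_end: float
    spike_times: np.ndarray  # sorted spike times (s), all neurons pooled
    spike_neurons: np.ndarray
    snapshots: dict[float, np.ndarray] = dc_field(default_factory=dict)
    flagged: int = 0  # neurons that left the domain guard

    def rate(self, bin_width: float = 1e-3) -> tuple[np.ndarray, np.ndarray]:
        return binned_rate(self, bin_width)


def binned_rate(result: MCResult, bin_width: float = 1e-3):
    edges = np.arange(0.0, result.t_end + bin_width, bin_width)
    counts, _ = np.histogram(result.spike_times, bins=edges)
    t = 0.5 * (edges[:-1] + edges[1:])
    return t, counts / (result.n_neurons * bin_width)


def steady_rate(
    result: MCResult, t_from: float, t_to: float | None = None
) -> tuple[float, float]:
    """Mean rate over [t_from, t_to] and its standard error.

    The standard error uses the across-neuron variance of per-neuron spike
    counts, which is exact for independent neurons.
    """
    t_to = result.t_end if t_to is None else t_to
    sel = (result.spike_times >= t_from) & (result.spike_times < t_to)
    per_neuron = np.bincount(
        result.spike_neurons[sel], minlength=result.n_neurons
    )
    T = t_to - t_from
    rates = per_neuron / T
    return float(rates.mean()), float(rates.std(ddof=1) / np.sqrt(len(rates)))


def _normalise_inputs(model: NeuronModel, inputs) -> list[tuple[float, object]]:
    """inputs: rate, (rate, h), or list of (rate, h); h None -> model rule."""
    if np.isscalar(inputs):
        return [(float(inputs), None)]
    if isinstance(inputs, tuple) and np.isscalar(inputs[0]):
        return [(float(inputs[0]), inputs[1])]
    return [(float(r), h) for r, h in inputs]


def _jump_vectors(model: NeuronModel, h, states: np.ndarray) -> np.ndarray:
    if h is None:
        if model.jump_rule is None:
            raise ValueError("no efficacy given and the model has no jump rule")
        return model.jump_rule(states)
    h = np.asarray(h, dtype=float)
    if h.ndim == 0:
        vec = np.zeros(2)
        vec[0 if model.jump_dimension == "v" else 1] = float(h)
        h = vec
    return np.broadcast_to(h, (len(states), 2))


def simulate(
    model: NeuronModel,
    n_neurons: int,
    inputs,
    t_end: float,
    dt_mc: float = 1e-5,
    seed: int = 0,
    init=None,
    snapshot_times=(),
    g_max: float | None = None,
    domain_guard: float = 1e6,
    mesh_dt: float | None = None,
) -> MCResult:
    """Simulate ``n_neurons`` independent neurons under Poisson spike trains.

    ``inputs`` is a rate (Hz), a (rate, efficacy) pair, or a list of such
    pairs; a scalar efficacy jumps the model's declared jump dimension, a
    2-vector jumps both coordinates, ``None`` invokes the model's
    state-dependent jump rule.  ``init`` is a single state or an (n, 2)
    array.  ``g_max`` clips the second coordinate (reflecting boundary).
    """
    if mesh_dt is not None and dt_mc > mesh_dt / 5 + 1e-18:
        raise ValueError("dt_mc must be at most a fifth of the mesh time step")
    rng = np.random.default_rng(seed)
    streams = _normalise_inputs(model, inputs)
    if init is None:
        init = np.zeros(2)
    states = np.array(np.broadcast_to(np.asarray(init, float), (n_neurons, 2)))
    snapshot_times = sorted(float(t) for t in snapshot_times)
    exact = model.flow is not None and model.refractory == 0.0
    if exact:
        return _simulate_exact(
            model, states, streams, t_end, rng, snapshot_times, g_max
        )
    return _simulate_stepped(
        model, states, streams, t_end, dt_mc, rng, snapshot_times, g_max,
        domain_guard,
    )


def _apply_threshold(model, states, t_now, spikes_t, spikes_n, active=None):
    if model.threshold_v is None:
        return
    crossed = states[:, 0] >= model.threshold_v
    if active is not None:
        crossed &= active
    if crossed.any():
        idx = np.nonzero(crossed)[0]
        spikes_t.extend([t_now] * len(idx) if np.isscalar(t_now) else t_now[idx])
        spikes_n.extend(idx)
        states[idx, 0] = model.reset_v
        states[idx, 1] += model.reset_w_increment


def _simulate_exact(model, states, streams, t_end, rng, snapshot_times, g_max):
    n = len(states)
    rates = np.array([r for r, _ in streams])
    lam = float(rates.sum())
    t_now = np.zeros(n)
    spikes_t: list[float] = []
    spikes_n: list[int] = []
    snaps: dict[float, np.ndarray] = {}
    checkpoints = list(snapshot_times) + [t_end]

    def advance(idx: np.ndarray, dtv: np.ndarray) -> None:
        """Flow neurons ``idx`` forward by ``dtv``, emitting drift-driven spikes."""
        if model.time_to_threshold is None or model.threshold_v is None:
            states[idx] = model.flow(states[idx], dtv)
            t_now[idx] += dtv
            return
        idx = idx.copy()
        dtv = dtv.copy()
        while len(idx):
            ttt = model.time_to_threshold(states[idx])
            fire = ttt < dtv - 1e-18
            calm = ~fire
            if calm.any():
                ci = idx[calm]
                states[ci] = model.flow(states[ci], dtv[calm])
                t_now[ci] += dtv[calm]
            f = idx[fire]
            if len(f) == 0:
                break
            tc = t_now[f] + ttt[fire]
            spikes_t.extend(tc.tolist())
            spikes_n.extend(f.tolist())
            states[f, 0] = model.reset_v
            states[f, 1] += model.reset_w_increment
            t_now[f] = tc
            dtv = dtv[fire] - ttt[fire]
            idx = f

    for cp in checkpoints:
        while True:
            behind = np.nonzero(t_now < cp - 1e-15)[0]
            if len(behind) == 0:
                break
            if lam <= 0:
                advance(behind, cp - t_now[behind])
                continue
            gaps = rng.exponential(1.0 / lam, size=len(behind))
            t_event = t_now[behind] + gaps
            arrives = t_event <= cp
            park = behind[~arrives]
            if len(park):
                advance(park, cp - t_now[park])
            hit = behind[arrives]
            if len(hit):
                advance(hit, t_event[arrives] - t_now[hit])
                if len(streams) == 1:
                    chosen = np.zeros(len(hit), dtype=int)
                else:
                    chosen = rng.choice(len(streams), size=len(hit), p=rates / lam)
                for s_idx, (_, h) in enumerate(streams):
                    mask = chosen == s_idx
                    if mask.any():
                        sub = hit[mask]
                        states[sub] += _jump_vectors(model, h, states[sub])
                if g_max is not None:
                    np.minimum(states[:, 1], g_max, out=states[:, 1])
                if model.name == "tm":
                    np.clip(states, 0.0, 1.0, out=states)
                _apply_threshold(model, states, t_now, spikes_t, spikes_n)
        if cp in snapshot_times:
            snaps[cp] = states.copy()
    st = np.array(spikes_t)
    sn = np.array(spikes_n, dtype=int)
    if len(st):
        order = np.argsort(st)
        st, sn = st[order], sn[order]
    return MCResult(
        model=model.name, n_neurons=n, t_end=t_end,
        spike_times=st, spike_neurons=sn, snapshots=snaps,
    )


def _rk4(model, states, dt):
    k1 = model.field(states)
    k2 = model.field(states + 0.5 * dt * k1)
    k3 = model.field(states + 0.5 * dt * k2)
    k4 = model.field(states + dt * k3)
    return states + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)


def _simulate_stepped(
    model, states, streams, t_end, dt_mc, rng, snapshot_times, g_max,
    domain_guard,
):
    n = len(states)
    n_steps = int(round(t_end / dt_mc))
    refr = np.zeros(n)
    spikes_t: list[float] = []
    spikes_n: list[int] = []
    snaps: dict[float, np.ndarray] = {}
    snap_steps = {int(round(t / dt_mc)): t for t in snapshot_times}
    flagged = np.zeros(n, dtype=bool)
    for k in range(n_steps):
        t = k * dt_mc
        for rate, h in streams:
            if rate <= 0:
                continue
            cnt = rng.poisson(rate * dt_mc, n)
            mx = int(cnt.max())
            for _ in range(mx):
                mask = cnt > 0
                if model.jump_dimension == "state" or h is None:
                    jv = _jump_vectors(model, h, states[mask])
                    states[mask] += jv
                else:
                    jv = _jump_vectors(model, h, states[mask])
                    states[mask] += jv
                cnt -= mask.astype(int)
                np.clip(cnt, 0, None, out=cnt)
        if g_max is not None:
            np.minimum(states[:, 1], g_max, out=states[:, 1])
        if model.name == "tm":
            np.clip(states, 0.0, 1.0, out=states)
        active = refr <= 0
        new_states = _rk4(model, states, dt_mc)
        # during refraction v is pinned but w keeps evolving
        states[:, 1] = new_states[:, 1]
        states[active, 0] = new_states[active, 0]
        refr -= dt_mc
        if model.threshold_v is not None:
            crossed = active & (states[:, 0] >= model.threshold_v)
            if crossed.any():
                idx = np.nonzero(crossed)[0]
                spikes_t.extend([t + dt_mc] * len(idx))
                spikes_n.extend(idx.tolist())
                states[idx, 0] = model.reset_v
                states[idx, 1] += model.reset_w_increment
                refr[idx] = model.refractory
        bad = np.abs(states).max(axis=1) > domain_guard
        if bad.any():
            flagged |= bad
            states[bad] = np.clip(states[bad], -domain_guard, domain_guard)
        if k + 1 in snap_steps:
            snaps[snap_steps[k + 1]] = states.copy()
    st = np.array(spikes_t)
    sn = np.array(spikes_n, dtype=int)
    return MCResult(
        model=model.name, n_neurons=n, t_end=t_end,
        spike_times=st, spike_neurons=sn, snapshots=snaps,
        flagged=int(flagged.sum()),
    )
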