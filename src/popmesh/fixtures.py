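"""Deterministic scenario builders for tests, demos and benchmarks.

Each fixture returns a dict bundling everything needed to run a scenario:
the mesh, its transition matrices, the reversal/reset mappings, the model
and a few scenario constants.  All randomness flows from a single seed
split into named streams (mesh, matrix, marginal, mc), so each component is
independently reproducible.

The `*_paper`-free scenario names describe the benchmark conditions:

* ``toy_2strip``   — 2 strips x 3 cells + 1 stationary cell, hand-checkable.
* ``lattice_1d``   — uniform 1D lattice where overlap fractions have closed
  forms: the exact oracle for the Monte-Carlo transition builder.
* ``ring_cycle``   — synthetic planar field with the unit circle as limit
  cycle (r' = r(1-r), theta' = 1).
* ``lif_benchmark``— LIF population, tau = 50 ms, Poisson 800 Hz, h = 0.03,
  V in [-1, 1): the standard steady-state density/rate benchmark.
* ``qif_grid``     — bursting QIF (F = V^2 + 1), threshold 10, reset -10.
* ``cond``         — conductance-based model (Table constants), jump
  calibration dg = 0.05 per mV of quoted efficacy, optional reflecting
  boundary at g_max.
* ``adexp``        — adaptive-exponential neuron, jumps in V, spike-triggered
  adaptation b.
* ``eif_1d``       — exponential neuron restricted to w = 0 (gain-curve
  reference without adaptation).
* ``fhn``          — Fitzhugh-Nagumo at I = 0.5 with a limit-cycle ring and
  a stationary region tiled around the slow central branch.
* ``tm``           — facilitating Tsodyks-Markram synapse population with
  the state-dependent jump rule.
"""

from __future__ import annotations

import numpy as np

from .geometry import QuadCell
from .mesh import (
    MappingTable,
    Mesh,
    build_limit_cycle_ring,
    build_mesh,
    build_reversal_mapping,
    conductance_seed_line,
    detect_stationary_region,
    integrate_characteristics,
    repair_degenerate,
)
from .models import NeuronModel, get_model
from .transition import (
    CellLocator,
    build_threshold_reset_mapping,
    build_transition_matrix,
)

__all__ = ["make_fixture", "seed_streams", "FIXTURE_NAMES"]

#: conductance jump per mV of quoted synaptic efficacy (the calibration
#: reproducing the reference firing rates at 3 kHz input)
COND_DG_PER_MV = 0.05


def seed_streams(seed: int) -> dict[str, int]:
    """Derive independent sub-seeds (below 2^31) for the named RNG streams."""
    ss = np.random.SeedSequence(seed)
    kids = ss.generate_state(4) % (2 ** 31)
    return {
        "mesh": int(kids[0]),
        "matrix": int(kids[1]),
        "marginal": int(kids[2]),
        "mc": int(kids[3]),
    }


def _rect(x0, x1, y0, y1, i, j) -> QuadCell:
    return QuadCell(
        np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]]), i, j
    )


# ---------------------------------------------------------------------------
# toy fixtures
# ---------------------------------------------------------------------------

def _toy_2strip(seed: int = 0, **_) -> dict:
    mesh = Mesh(dt=1e-3)
    mesh.add_stationary_cell(
        np.array([[-1.0, 0.0], [0.0, 0.0], [0.0, 1.0], [-1.0, 1.0]])
    )
    mesh.add_strip([_rect(k, k + 1, 0, 1, 1, k) for k in range(3)])
    mesh.add_strip([_rect(k, k + 1, 1, 2, 2, k) for k in range(3)])
    reversal = build_reversal_mapping(mesh)
    return {"mesh": mesh, "reversal": reversal, "reset": None}


def _lattice_1d(
    seed: int = 0, n_cells: int = 50, v0: float = 0.0, v1: float = 1.0,
    w_band: float = 1.0, **_
) -> dict:
    """Uniform 1D lattice with closed-form overlap fractions.

    For a jump of h along v, a cell [a, a+d) lands on cells j+m and j+m+1
    with exact fractions (1 - frac(h/d)) and frac(h/d).
    """
    d = (v1 - v0) / n_cells
    mesh = Mesh(dt=1e-3)
    mesh.add_strip(
        [_rect(v0 + k * d, v0 + (k + 1) * d, 0.0, w_band, 1, k) for k in range(n_cells)]
    )

    def exact_alpha(h: float, j: int) -> dict[tuple[int, int], float]:
        s = h / d
        m = int(np.floor(s))
        f = s - m
        out = {}
        for off, frac in ((m, 1.0 - f), (m + 1, f)):
            tj = j + off
            tj = min(max(tj, 0), n_cells - 1)  # clipped at the lattice edge
            if frac > 0:
                out[(1, tj)] = out.get((1, tj), 0.0) + frac
        return out

    return {"mesh": mesh, "cell_width": d, "exact_alpha": exact_alpha,
            "reversal": None, "reset": None}


def _circle_model() -> NeuronModel:
    def field(p):
        p = np.asarray(p, dtype=float)
        x, y = p[..., 0], p[..., 1]
        r = np.hypot(x, y)
        shrink = 1.0 - r
        return np.stack([x * shrink - y, y * shrink + x], axis=-1)

    return NeuronModel(name="circle", field=field, jump_dimension="v")


def _ring_cycle(seed: int = 0, epsilon: float = 0.05, n_ring: int = 64, **_) -> dict:
    """Synthetic limit-cycle scenario: unit circle attractor of r' = r(1-r)."""
    model = _circle_model()
    dt = 2 * np.pi / n_ring
    theta = np.arange(n_ring) * dt  # analytic cycle: unit circle, theta' = 1
    cycle = np.stack([np.cos(theta), np.sin(theta)], axis=-1)
    # strips approach the circle from outside and inside
    seeds_out = np.stack(
        [2.0 * np.cos(theta[::8]), 2.0 * np.sin(theta[::8])], axis=-1
    )
    seeds_in = np.stack(
        [0.25 * np.cos(theta[::8]), 0.25 * np.sin(theta[::8])], axis=-1
    )
    mesh = Mesh(dt=dt)
    for seeds in (seeds_out, seeds_in):
        chars = integrate_characteristics(model, seeds, dt, 3.0)
        for a in range(len(seeds)):
            b = (a + 1) % len(seeds)
            c0, c1 = chars[a], chars[b]
            # truncate where the characteristic is within epsilon of the cycle
            r0 = np.hypot(c0[:, 0], c0[:, 1])
            r1 = np.hypot(c1[:, 0], c1[:, 1])
            good = np.nonzero(
                (np.abs(r0 - 1.0) > epsilon) & (np.abs(r1 - 1.0) > epsilon)
            )[0]
            stop = good[-1] + 1 if len(good) else 0
            from .mesh import _cells_from_pair

            quads = _cells_from_pair(c0[: stop + 1], c1[: stop + 1], 1e-9, None)
            if quads:
                mesh.add_strip([QuadCell(q, 0, jj) for jj, q in enumerate(quads)])
    ring, mapping = build_limit_cycle_ring(mesh, model, epsilon, cycle=cycle)
    return {
        "mesh": mesh, "model": model, "ring": ring, "reversal": mapping,
        "reset": None, "cycle": cycle, "epsilon": epsilon,
    }


# ---------------------------------------------------------------------------
# 1D neuron benchmarks
# ---------------------------------------------------------------------------

def _lif_benchmark(
    seed: int = 0,
    n_point: int = 10_000,
    dt: float = 1e-4,
    h: float = 0.03,
    nu: float = 800.0,
    area_min_frac: float = 0.01,
    include_negative: bool = True,
    **_,
) -> dict:
    """LIF population: tau = 50 ms, rescaled threshold 1, reset 0."""
    streams = seed_streams(seed)
    model = get_model("lif", tau=0.05)
    w_band = 1.0
    # area cut stops the strips near V = 0 where cells shrink geometrically
    area_min = area_min_frac * dt / model.tau * w_band
    seed_lines = [[(1.0, 0.0), (1.0, w_band)]]
    if include_negative:
        seed_lines.append([(-1.0, 0.0), (-1.0, w_band)])
    mesh = build_mesh(
        model, seed_lines, dt, t_end=0.6, area_min=area_min,
        threshold_v=model.threshold_v,
    )
    # stationary (reversal) bins bridge the gap the area cut left around the
    # fixed point; they are split at V = 0 because the population's support
    # is [0, 1) (reset at 0, excitatory jumps) and the reversal bin's extent
    # decides where its mass lands in marginal distributions
    v_hi = mesh.strips[0].cells[-1].vertices[:, 0].min()
    v_lo = (
        mesh.strips[1].cells[-1].vertices[:, 0].max()
        if include_negative
        else -v_hi
    )
    mesh.add_stationary_cell(
        np.array([[0.0, 0.0], [v_hi, 0.0], [v_hi, w_band], [0.0, w_band]])
    )
    mesh.add_stationary_cell(
        np.array([[v_lo, 0.0], [0.0, 0.0], [0.0, w_band], [v_lo, w_band]])
    )
    reversal = build_reversal_mapping(mesh)
    locator = CellLocator(mesh)
    reset = build_threshold_reset_mapping(
        mesh, model.threshold_v, model.reset_v, 0.0, locator=locator
    )
    matrix = build_transition_matrix(
        mesh, (h, 0.0), n_point=n_point, seed=streams["matrix"],
        threshold_v=model.threshold_v, locator=locator, mesh_id="lif",
    )
    return {
        "mesh": mesh, "model": model, "reversal": reversal, "reset": reset,
        "matrix": matrix, "nu": nu, "h": h, "locator": locator,
        "streams": streams,
    }


def _qif_grid(
    seed: int = 0,
    n_point: int = 5000,
    dt: float = 1e-4,
    h: float = 0.05,
    tau: float = 0.01,
    I_c: float = 1.0,
    **_,
) -> dict:
    """Bursting QIF: single strip from reset to threshold, no stationary cell."""
    streams = seed_streams(seed)
    model = get_model("qif", tau=tau, I_c=I_c)
    w_band = 1.0
    # transit time from reset to threshold is finite: tau*(atan(10)-atan(-10))
    t_transit = tau * (
        np.arctan(model.threshold_v) - np.arctan(model.reset_v)
    ) / np.sqrt(I_c)
    mesh = build_mesh(
        model,
        [[(model.reset_v, 0.0), (model.reset_v, w_band)]],
        dt,
        t_end=t_transit + 5 * dt,
        area_min=0.0,
        threshold_v=model.threshold_v,
    )
    locator = CellLocator(mesh)
    reset = build_threshold_reset_mapping(
        mesh, model.threshold_v, model.reset_v, 0.0, locator=locator
    )
    matrix = build_transition_matrix(
        mesh, (h, 0.0), n_point=n_point, seed=streams["matrix"],
        threshold_v=model.threshold_v, locator=locator, mesh_id="qif",
    )
    return {
        "mesh": mesh, "model": model, "reversal": MappingTable("reversal"),
        "reset": reset, "matrix": matrix, "h": h, "locator": locator,
        "streams": streams,
    }


def _eif_1d(
    seed: int = 0,
    n_point: int = 5000,
    dt: float = 1e-4,
    h: float = 1.0,
    v_left: float = -80.0,
    threshold_v: float = -40.0,
    **_,
) -> dict:
    """Exponential integrate-and-fire (AdExp at w = 0): 3 strips, 2 fixed points."""
    streams = seed_streams(seed)
    model = get_model("eif", threshold_v=threshold_v)
    c = model.params
    w_band = 1.0
    # locate the two fixed points of the 1D field
    from scipy.optimize import brentq

    def f(v):
        return float(model.field(np.array([v, 0.0]))[0])

    v_stable = brentq(f, v_left, c["V_T"])
    v_unstable = brentq(f, c["V_T"], threshold_v - 1e-6)
    gap = 0.3  # mV clearance around the fixed points
    area_min = 0.003 * dt / model.tau * w_band
    mesh = build_mesh(
        model,
        [
            [(v_left, 0.0), (v_left, w_band)],                    # -> stable eq
            [(v_unstable - gap, 0.0), (v_unstable - gap, w_band)],  # back to eq
            [(v_unstable + gap, 0.0), (v_unstable + gap, w_band)],  # spike run
        ],
        dt,
        t_end=0.4,
        area_min=area_min,
        threshold_v=threshold_v,
        v_ceiling=threshold_v + 3.0,
    )
    # stationary bins at the stable equilibrium and the unstable point
    lo1 = mesh.strips[0].cells[-1].vertices[:, 0].max()
    hi1 = mesh.strips[1].cells[-1].vertices[:, 0].min()
    if lo1 > hi1:
        lo1, hi1 = hi1, lo1
    mesh.add_stationary_cell(
        np.array([[lo1, 0.0], [hi1, 0.0], [hi1, w_band], [lo1, w_band]])
    )
    mesh.add_stationary_cell(
        np.array(
            [
                [v_unstable - gap, 0.0],
                [v_unstable + gap, 0.0],
                [v_unstable + gap, w_band],
                [v_unstable - gap, w_band],
            ]
        )
    )
    reversal = build_reversal_mapping(mesh)
    locator = CellLocator(mesh)
    reset = build_threshold_reset_mapping(
        mesh, threshold_v, model.reset_v, 0.0, locator=locator
    )
    matrix = build_transition_matrix(
        mesh, (h, 0.0), n_point=n_point, seed=streams["matrix"],
        threshold_v=threshold_v, locator=locator, mesh_id="eif",
    )
    return {
        "mesh": mesh, "model": model, "reversal": reversal, "reset": reset,
        "matrix": matrix, "h": h, "locator": locator, "streams": streams,
        "v_stable": v_stable, "v_unstable": v_unstable,
    }


# ---------------------------------------------------------------------------
# 2D benchmarks
# ---------------------------------------------------------------------------

def _cond(
    seed: int = 0,
    J_mv: float = 1.0,
    g_max: float | None = None,
    n_point: int = 10_000,
    dt: float = 2e-4,
    dg_seed: float = 0.02,
    g_top: float = 2.0,
    v_min: float = -66.0,
    area_min: float = 2e-5,
    t_end_char: float = 0.2,
    **_,
) -> dict:
    """Conductance-based population; jumps of dg = 0.05 per mV of efficacy.

    With ``g_max`` set, the mesh is clipped at the maximum conductance and
    jump events beyond it are reassigned to the boundary cells along the
    jump direction — a reflecting boundary.
    """
    streams = seed_streams(seed)
    model = get_model("cond")
    top = g_max if g_max is not None else g_top
    n_g = int(round(top / dg_seed))
    left = conductance_seed_line(v_min, n_g, dg_seed)
    # characteristics from the upper boundary sweep the region beneath it;
    # without them the high-g band next to threshold would be uncovered
    v_top = np.arange(v_min + 0.4, model.threshold_v - 0.4, 0.4)
    topline = np.stack([v_top, np.full_like(v_top, top)], axis=-1)
    seeds = np.vstack([left, topline])
    mesh = build_mesh(
        model, [seeds], dt, t_end=t_end_char, area_min=area_min,
        threshold_v=model.threshold_v,
    )
    # reversal bin: a small quadrilateral at the equilibrium (E_l, 0)
    e_l = model.params["E_l"]
    mesh.add_stationary_cell(
        np.array(
            [[e_l - 0.15, 0.0], [e_l + 0.15, 0.0],
             [e_l + 0.15, 0.004], [e_l - 0.15, 0.004]]
        )
    )
    reversal = build_reversal_mapping(mesh)
    locator = CellLocator(mesh)
    reset = build_threshold_reset_mapping(
        mesh, model.threshold_v, model.reset_v, 0.0, locator=locator
    )
    dg = COND_DG_PER_MV * J_mv
    matrix = build_transition_matrix(
        mesh, (0.0, dg), n_point=n_point, seed=streams["matrix"],
        threshold_v=model.threshold_v, locator=locator,
        mesh_id=f"cond_gmax{g_max}" if g_max else "cond",
    )
    return {
        "mesh": mesh, "model": model, "reversal": reversal, "reset": reset,
        "matrix": matrix, "dg": dg, "g_max": g_max, "locator": locator,
        "streams": streams,
    }


def _adexp(
    seed: int = 0,
    n_point: int = 2000,
    dt: float = 5e-4,
    w_lo: float = -30.0,
    w_hi: float = 550.0,
    v_left: float = -85.0,
    threshold_v: float = -40.0,
    area_min: float = 2e-3,
    n_w_left: int = 17,
    n_w_interior: int = 33,
    n_w_spike: int = 21,
    **_,
) -> dict:
    """Adaptive-exponential neuron with spike-triggered adaptation b.

    The phase plane dictates three strip families.  (1) *left*: forward from
    the left edge into the basin of the stable equilibrium.  (2) *interior*:
    the region between the V-nullcline and the separatrix — the stable
    manifold of the saddle, traced here by backward integration along its
    stable eigendirection — is fed by flow hugging the separatrix, so strips
    are integrated forward from seeds just left of it; they sweep to the
    nullcline and slide down it, carrying the slow adaptation decay.
    (3) *spike*: backward from just above the threshold line, covering the
    run-away region right of the separatrix.  Left strips hand mass to the
    interior family; interior strips reverse into the equilibrium bin.  The
    narrow clefts along the separatrix are forbidden to the deterministic
    flow; jump events landing there are reassigned along the jump direction.
    """
    from scipy.optimize import root as _root

    from .mesh import _cells_from_pair

    streams = seed_streams(seed)
    model = get_model("adexp", threshold_v=threshold_v)
    c = model.params

    # saddle point and its stable manifold (the separatrix)
    saddle = _root(lambda x: model.field(x), np.array([-45.0, 100.0])).x
    eps = 1e-5
    J = np.zeros((2, 2))
    for k in range(2):
        d = np.zeros(2)
        d[k] = eps
        J[:, k] = (model.field(saddle + d) - model.field(saddle - d)) / (2 * eps)
    ev, evec = np.linalg.eig(J)
    vs = evec[:, int(np.argmin(ev.real))].real
    vs /= np.linalg.norm(vs)
    branches = [
        integrate_characteristics(
            model, [saddle + s * 0.5 * vs], 1e-3, 1.0, "backward",
            rtol=1e-8, atol=1e-9, v_ceiling=threshold_v + 3.0,
        )[0]
        for s in (+1.0, -1.0)
    ]
    manifold = np.vstack(branches + [saddle[None, :]])
    order = np.argsort(manifold[:, 1])
    mw, mv = manifold[order, 1], manifold[order, 0]

    def v_sep(w):
        return np.interp(w, mw, mv)

    mesh = Mesh(dt=dt)
    groups: dict[str, list[int]] = {}

    def add_line(name, seeds, direction, t_end):
        chars = integrate_characteristics(
            model, seeds, dt, t_end, direction,
            rtol=1e-8, atol=1e-9, v_ceiling=threshold_v + 3.0,
        )
        idxs = []
        for a in range(len(seeds) - 1):
            quads = _cells_from_pair(chars[a], chars[a + 1], area_min, threshold_v)
            if direction == "backward":
                quads = quads[::-1]
            if quads:
                s = mesh.add_strip([QuadCell(q, 0, j) for j, q in enumerate(quads)])
                idxs.append(s.strip_index)
        groups[name] = idxs

    ws = np.linspace(w_lo, w_hi, n_w_left)
    add_line(
        "left", np.stack([np.full_like(ws, v_left), ws], axis=-1),
        "forward", 0.12,
    )
    wi = np.linspace(w_lo + 10.0, w_hi, n_w_interior)
    add_line(
        "interior",
        np.stack([v_sep(wi) - 0.35, wi], axis=-1),
        "forward", 0.8,
    )
    wr = np.linspace(w_lo, w_hi, n_w_spike)
    add_line(
        "spike", np.stack([np.full_like(wr, threshold_v + 1.0), wr], axis=-1),
        "backward", 0.06,
    )
    # Trajectories merge onto the V-nullcline (their across-strip width
    # collapses, so the area cut ends them there).  The slow slide down the
    # nullcline carries the adaptation decay and is meshed as a dedicated
    # one-dimensional channel strip of fixed width; the other families hand
    # their mass to it through the reversal mapping.
    chan_w = 0.7  # half-width of the channel in mV
    chan_char = integrate_characteristics(
        model, [[v_sep(w_hi) - 8.0, w_hi]], dt, 1.0,
        rtol=1e-8, atol=1e-9, v_ceiling=threshold_v + 3.0,
    )[0]
    keep = np.nonzero(chan_char[:, 1] > 1.0)[0]
    chan_char = chan_char[: keep[-1] + 1] if len(keep) else chan_char[:2]
    quads = [
        np.array(
            [
                [chan_char[k, 0] - chan_w, chan_char[k, 1]],
                [chan_char[k + 1, 0] - chan_w, chan_char[k + 1, 1]],
                [chan_char[k + 1, 0] + chan_w, chan_char[k + 1, 1]],
                [chan_char[k, 0] + chan_w, chan_char[k, 1]],
            ]
        )
        for k in range(len(chan_char) - 1)
    ]
    chan_strip = mesh.add_strip([QuadCell(q, 0, j) for j, q in enumerate(quads)])
    groups["channel"] = [chan_strip.strip_index]
    mesh, extra = repair_degenerate(mesh, area_min=0.0)
    e_l = c["E_l"]
    mesh.add_stationary_cell(
        np.array(
            [[e_l - 0.4, -4.0], [e_l + 0.4, -4.0],
             [e_l + 0.4, 4.0], [e_l - 0.4, 4.0]]
        )
    )
    # reversal: left and interior strips merge into the nullcline channel at
    # matching w; the channel and the spike family reverse into the
    # equilibrium bin
    chan_cells = mesh.strips[groups["channel"][0] - 1].cells
    chan_wc = np.array([cl.centroid[1] for cl in chan_cells])
    reversal = MappingTable("reversal")
    for strip in mesh.strips:
        if strip.strip_index in groups["left"] or (
            strip.strip_index in groups["interior"]
        ):
            end = strip.cells[-1].centroid
            t = chan_cells[int(np.argmin(np.abs(chan_wc - end[1])))]
            reversal.entries.append(
                ((strip.strip_index, 0), (t.strip_index, t.cell_index), 1.0)
            )
        else:
            reversal.entries.append(((strip.strip_index, 0), (0, 0), 1.0))
    reversal.extend(extra)
    locator = CellLocator(mesh)
    reset = build_threshold_reset_mapping(
        mesh, threshold_v, model.reset_v, model.reset_w_increment,
        n_point=2000, seed=streams["matrix"] + 1, locator=locator,
    )
    matrix = build_transition_matrix(
        mesh, (1.0, 0.0), n_point=n_point, seed=streams["matrix"],
        threshold_v=threshold_v, locator=locator, mesh_id="adexp",
    )
    return {
        "mesh": mesh, "model": model, "reversal": reversal, "reset": reset,
        "matrix": matrix, "locator": locator, "streams": streams,
        "groups": groups,
    }


def _fhn(
    seed: int = 0,
    I: float = 0.5,
    n_point: int = 2000,
    epsilon: float = 0.08,
    dt: float = 0.05,
    speed_min: float = 0.1,
    J: float = 0.1,
    **_,
) -> dict:
    """Fitzhugh-Nagumo at I = 0.5: limit-cycle ring plus stationary interior."""
    streams = seed_streams(seed)
    model = get_model("fhn", I=I)
    from .mesh import _cells_from_pair, find_limit_cycle

    cycle = find_limit_cycle(model, (2.0, 0.0), t_transient=60.0,
                             t_search=60.0, dt_sample=dt, tol=5e-3)

    def clipped_strips(mesh, seeds, t_int):
        chars = integrate_characteristics(model, seeds, dt, t_int)
        for a in range(len(seeds) - 1):
            c0, c1 = chars[a], chars[a + 1]
            d0 = np.min(
                np.linalg.norm(c0[:, None, :] - cycle[None, :, :], axis=2), axis=1
            )
            d1 = np.min(
                np.linalg.norm(c1[:, None, :] - cycle[None, :, :], axis=2), axis=1
            )
            outside = np.nonzero((d0 > epsilon) & (d1 > epsilon))[0]
            stop = outside[-1] + 1 if len(outside) else 0
            quads = _cells_from_pair(c0[: stop + 1], c1[: stop + 1], 1e-7, None)
            if quads:
                mesh.add_strip([QuadCell(q, 0, jj) for jj, q in enumerate(quads)])

    mesh = Mesh(dt=dt)
    # outer strips: seeds on the bounding box flowing onto the cycle
    n_edge = 8
    box = []
    for s in np.linspace(-2.5, 2.5, n_edge):
        box.append((s, 2.2))
        box.append((s, -1.2))
    box = sorted(box, key=lambda p: np.arctan2(p[1] - 0.5, p[0]))
    clipped_strips(mesh, np.array(box + [box[0]]), 30.0)
    # interior: stationary region around the slow central branch, then
    # strips from its (spline-smoothed) boundary out to the cycle
    boundary, stat_cells = detect_stationary_region(
        model, speed_min, (-1.1, -0.7, 0.5, 0.9), resolution=24
    )
    for c in stat_cells:
        mesh.add_stationary_cell(c.vertices)
    if len(boundary) >= 8:
        pick = boundary[:: max(1, len(boundary) // 12)]
        clipped_strips(mesh, np.vstack([pick, pick[:1]]), 30.0)
    mesh, extra = repair_degenerate(mesh, area_min=1e-7)
    ring, mapping = build_limit_cycle_ring(
        mesh, model, epsilon, cycle=cycle, gap_factor=50.0
    )
    mapping.extend(extra)
    locator = CellLocator(mesh)
    matrix = build_transition_matrix(
        mesh, (J, 0.0), n_point=n_point, seed=streams["matrix"],
        locator=locator, mesh_id="fhn",
    )
    return {
        "mesh": mesh, "model": model, "reversal": mapping, "reset": None,
        "matrix": matrix, "ring": ring, "cycle": cycle, "locator": locator,
        "streams": streams,
    }


def _tm(
    seed: int = 0,
    n_point: int = 5000,
    dt: float = 2e-3,
    n_seeds: int = 16,
    area_min: float = 1e-6,
    **_,
) -> dict:
    """Facilitating TM synapses: state space [0,1]^2, state-dependent jumps."""
    streams = seed_streams(seed)
    model = get_model("tm")
    us = np.linspace(0.0, 0.96, n_seeds + 1)
    seeds = np.stack([np.zeros_like(us), us], axis=-1)
    mesh = build_mesh(model, [seeds], dt, t_end=1.2, area_min=area_min)
    # after r has recovered (r -> 1) the dynamics is one-dimensional in u;
    # a channel strip along the r = 1 edge carries the slow facilitation
    # decay that the area-cut strips cannot resolve
    tau_facil = model.params["tau_facil"]
    u_top = 0.96
    u_ch = [u_top]
    while u_ch[-1] > 0.004:
        u_ch.append(u_ch[-1] * np.exp(-dt / tau_facil))
    chan = mesh.add_strip(
        [
            QuadCell(
                np.array(
                    [[0.99, u_ch[k + 1]], [1.0, u_ch[k + 1]],
                     [1.0, u_ch[k]], [0.99, u_ch[k]]]
                ),
                0, k,
            )
            for k in range(len(u_ch) - 1)
        ]
    )
    # stationary bin at the rest state (r, u) = (1, 0)
    mesh.add_stationary_cell(
        np.array([[0.985, 0.0], [1.0, 0.0], [1.0, 0.01], [0.985, 0.01]])
    )
    chan_cells = chan.cells
    chan_u = np.array([cl.centroid[1] for cl in chan_cells])
    reversal = MappingTable("reversal")
    for strip in mesh.strips:
        if strip.strip_index == chan.strip_index:
            reversal.entries.append(((strip.strip_index, 0), (0, 0), 1.0))
            continue
        end = strip.cells[-1].centroid
        t = chan_cells[int(np.argmin(np.abs(chan_u - end[1])))]
        reversal.entries.append(
            ((strip.strip_index, 0), (t.strip_index, t.cell_index), 1.0)
        )
    locator = CellLocator(mesh)
    matrix = build_transition_matrix(
        mesh, model.jump_rule, n_point=n_point, seed=streams["matrix"],
        locator=locator, mesh_id="tm", jump_label="rule tm U=0.1",
    )
    return {
        "mesh": mesh, "model": model, "reversal": reversal, "reset": None,
        "matrix": matrix, "locator": locator, "streams": streams,
    }


_FIXTURES = {
    "toy_2strip": _toy_2strip,
    "lattice_1d": _lattice_1d,
    "ring_cycle": _ring_cycle,
    "lif_benchmark": _lif_benchmark,
    "qif_grid": _qif_grid,
    "eif_1d": _eif_1d,
    "cond": _cond,
    "adexp": _adexp,
    "fhn": _fhn,
    "tm": _tm,
}

FIXTURE_NAMES = sorted(_FIXTURES)


def make_fixture(name: str, seed: int = 0, **overrides) -> dict:
    """Build a named scenario; unknown names list the available ones."""
    try:
        f = _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {FIXTURE_NAMES}"
        ) from None
    return f(seed=seed, **overrides)
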