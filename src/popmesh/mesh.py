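"""State-space mesh construction from characteristics.

A mesh is a set of *strips*: ordered sequences of simple quadrilateral cells
bounded by two neighbouring characteristics of the model's vector field,
sampled every ``dt`` seconds.  Flow order is built in: mass in cell j of a
strip at time t is in cell j+1 at t + dt.  Strip 0 is reserved for
stationary cells (fixed points, quasi-static regions, reversal bins), whose
mass does not move deterministically.

Construction stops a strip early when a cell drops below a minimum area or
becomes self-intersecting: boundaries of state space are approached through
regions of vanishing measure, so the area cut doubles as the boundary
detector.  Mass leaving the end of a strip is transferred by a *reversal
mapping* to a designated cell (a reversal bin, an equilibrium cell, or the
closest cell of a limit-cycle ring).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.integrate import solve_ivp
from scipy import ndimage
from scipy.interpolate import splev, splprep

from .geometry import (
    GeometryError,
    QuadCell,
    classify_quad,
    polygon_area,
)
from .models import NeuronModel

__all__ = [
    "Strip",
    "Mesh",
    "MappingTable",
    "EmptyStripError",
    "build_strip",
    "build_mesh",
    "build_reversal_mapping",
    "build_limit_cycle_ring",
    "detect_stationary_region",
    "repair_degenerate",
    "integrate_characteristics",
    "conductance_seed_line",
    "write_mesh",
    "read_mesh",
]

FLOAT_FMT = "%.17g"  # bit-exact text round-trip for doubles


class EmptyStripError(RuntimeError):
    """Raised when strip construction degenerates at the very first cell."""


@dataclass
class Strip:
    """An ordered run of quadrilateral cells between two characteristics."""

    strip_index: int
    cells: list[QuadCell]

    def __len__(self) -> int:
        return len(self.cells)


@dataclass
class Mesh:
    """Strips of cells plus the stationary cells of strip 0."""

    dt: float
    strips: list[Strip] = dc_field(default_factory=list)
    stationary_cells: list[QuadCell] = dc_field(default_factory=list)
    labels: tuple[str, str] = ("v", "w")
    #: strip indices forming closed rings (limit cycles); in-memory only
    closed_strips: set[int] = dc_field(default_factory=set)

    def __post_init__(self):
        self._check_indices()

    def _check_indices(self):
        got = [s.strip_index for s in self.strips]
        if got != list(range(1, len(self.strips) + 1)):
            raise ValueError(f"strip indices must be 1..N consecutive, got {got}")

    @property
    def n_strips(self) -> int:
        return len(self.strips)

    def n_cell(self, i: int) -> int:
        return len(self.stationary_cells) if i == 0 else len(self.strips[i - 1])

    @property
    def n_cells(self) -> int:
        return len(self.stationary_cells) + sum(len(s) for s in self.strips)

    def cell(self, i: int, j: int) -> QuadCell:
        if i == 0:
            return self.stationary_cells[j]
        return self.strips[i - 1].cells[j]

    def cells_lex(self):
        """All cells in (strip, cell) lexicographic order, strip 0 first."""
        yield from self.stationary_cells
        for s in self.strips:
            yield from s.cells

    def flat_index(self, i: int, j: int) -> int:
        off = len(self.stationary_cells)
        for s in self.strips[: i - 1] if i > 0 else []:
            off += len(s)
        return j if i == 0 else off + j

    def coords_lex(self) -> list[tuple[int, int]]:
        out = [(0, j) for j in range(len(self.stationary_cells))]
        for s in self.strips:
            out.extend((s.strip_index, j) for j in range(len(s)))
        return out

    def add_stationary_cell(self, vertices) -> QuadCell:
        c = QuadCell(np.asarray(vertices, float), 0, len(self.stationary_cells))
        self.stationary_cells.append(c)
        return c

    def add_strip(self, cells_or_strip, closed: bool = False) -> Strip:
        idx = len(self.strips) + 1
        cells = (
            cells_or_strip.cells
            if isinstance(cells_or_strip, Strip)
            else list(cells_or_strip)
        )
        renum = [
            QuadCell(c.vertices, idx, j) for j, c in enumerate(cells)
        ]
        strip = Strip(idx, renum)
        self.strips.append(strip)
        if closed:
            self.closed_strips.add(idx)
        return strip


@dataclass
class MappingTable:
    """Cell-to-cell mass remapping with fractions (reversal or reset kind)."""

    kind: str  # 'reversal' | 'reset'
    entries: list[tuple[tuple[int, int], tuple[int, int], float]] = dc_field(
        default_factory=list
    )

    def __post_init__(self):
        if self.kind not in ("reversal", "reset"):
            raise ValueError("kind must be 'reversal' or 'reset'")

    def sources(self) -> list[tuple[int, int]]:
        return sorted({src for src, _, _ in self.entries})

    def validate(self, mesh: Mesh, tol: float = 1e-9) -> None:
        sums: dict[tuple[int, int], float] = {}
        for src, tgt, frac in self.entries:
            if not (0.0 < frac <= 1.0 + tol):
                raise ValueError(f"fraction {frac} out of (0, 1] for {src}->{tgt}")
            ti, tj = tgt
            if ti > mesh.n_strips or tj >= mesh.n_cell(ti):
                raise ValueError(f"mapping target {tgt} not in mesh")
            sums[src] = sums.get(src, 0.0) + frac
        for src, s in sums.items():
            if abs(s - 1.0) > tol:
                raise ValueError(f"fractions for source {src} sum to {s}, not 1")

    def extend(self, other: "MappingTable") -> None:
        self.entries.extend(other.entries)


# ---------------------------------------------------------------------------
# characteristic integration
# ---------------------------------------------------------------------------

def integrate_characteristics(
    model: NeuronModel,
    seeds,
    dt: float,
    t_end: float,
    direction: str = "forward",
    rtol: float = 1e-10,
    atol: float = 1e-12,
    v_ceiling: float | None = None,
) -> np.ndarray:
    """Integrate the model field from each seed, sampled at multiples of dt.

    Returns an array of shape (n_seeds, n_steps + 1, 2).  All seeds are
    integrated jointly as one ODE system with a high-order adaptive solver
    (DOP853) and dense output at exact dt multiples.  ``direction='backward'``
    integrates the time-reversed field; the returned samples then run
    backward in real time (callers reverse cell order to restore flow order).

    ``v_ceiling`` freezes the v-motion of characteristics that have climbed
    past the given potential (spike runs of exponential models diverge in
    finite time; the frozen part lies beyond the threshold cut and never
    enters the mesh).
    """
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    if dt <= 0:
        raise ValueError("dt must be positive")
    sign = {"forward": 1.0, "backward": -1.0}[direction]
    n_steps = int(round(t_end / dt))
    t_eval = np.arange(n_steps + 1) * dt

    def rhs(t, y):
        s = y.reshape(-1, 2)
        d = sign * model.field(s)
        if v_ceiling is not None:
            d[(s[:, 0] >= v_ceiling) & (d[:, 0] > 0), 0] = 0.0
        return d.ravel()

    sol = solve_ivp(
        rhs,
        (0.0, t_eval[-1]),
        seeds.ravel(),
        t_eval=t_eval,
        method="DOP853",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"characteristic integration failed: {sol.message}")
    return sol.y.T.reshape(n_steps + 1, -1, 2).transpose(1, 0, 2)


def _cells_from_pair(
    c0: np.ndarray,
    c1: np.ndarray,
    area_min: float,
    threshold_v: float | None,
) -> list[np.ndarray]:
    """Build the vertex lists of a strip from two sampled characteristics.

    Stops at the first degenerate, complex or sub-area cell, or once a cell
    lies entirely beyond the threshold potential.
    """
    out: list[np.ndarray] = []
    for k in range(len(c0) - 1):
        quad = np.array([c0[k], c0[k + 1], c1[k + 1], c1[k]])
        if not np.all(np.isfinite(quad)):
            break
        if threshold_v is not None and np.all(quad[:, 0] > threshold_v):
            break
        try:
            kind = classify_quad(quad)
        except GeometryError:
            break
        if kind == "complex":
            break
        if abs(polygon_area(quad)) < area_min:
            break
        out.append(quad)
    return out


def build_strip(
    model: NeuronModel,
    seed0,
    seed1,
    dt: float,
    t_end: float,
    direction: str = "forward",
    area_min: float = 0.0,
    threshold_v: float | None = None,
    strip_index: int = 1,
) -> Strip:
    """Build one strip between the characteristics through seed0 and seed1."""
    seed0 = np.asarray(seed0, float)
    seed1 = np.asarray(seed1, float)
    if np.allclose(seed0, seed1):
        raise ValueError("seed points must differ")
    chars = integrate_characteristics(model, [seed0, seed1], dt, t_end, direction)
    quads = _cells_from_pair(chars[0], chars[1], area_min, threshold_v)
    if direction == "backward":
        quads = quads[::-1]
    if not quads:
        raise EmptyStripError("strip degenerate at the first cell")
    cells = [QuadCell(q, strip_index, j) for j, q in enumerate(quads)]
    return Strip(strip_index, cells)


def default_area_min(seed_lines, frac: float = 1e-6) -> float:
    """Area cut heuristic: ``frac`` x bounding-box area of the seed set."""
    pts = np.concatenate([np.atleast_2d(np.asarray(s, float)) for s in seed_lines])
    ext = pts.max(axis=0) - pts.min(axis=0)
    return frac * float(ext[0] * ext[1]) if np.all(ext > 0) else frac


def build_mesh(
    model: NeuronModel,
    seed_lines,
    dt: float,
    t_end: float,
    area_min: float | None = None,
    directions=None,
    threshold_v: float | None = None,
    labels: tuple[str, str] = ("v", "w"),
    check_overlap: bool = False,
    v_ceiling: float | None = None,
) -> Mesh:
    """Build a mesh from one or more seed lines.

    Each seed line is a sequence of >= 2 points; consecutive point pairs
    yield strips, numbered in creation order from 1.  ``directions`` gives
    one of 'forward'/'backward' per seed line (default all forward).
    Stationary cells are added separately by the caller.
    """
    seed_lines = [np.atleast_2d(np.asarray(s, float)) for s in seed_lines]
    if directions is None:
        directions = ["forward"] * len(seed_lines)
    if area_min is None:
        area_min = default_area_min(seed_lines)
    mesh = Mesh(dt=dt, labels=labels)
    for line, direction in zip(seed_lines, directions):
        if len(line) < 2:
            raise ValueError("each seed line needs at least 2 points")
        chars = integrate_characteristics(
            model, line, dt, t_end, direction, v_ceiling=v_ceiling
        )
        for a in range(len(line) - 1):
            quads = _cells_from_pair(chars[a], chars[a + 1], area_min, threshold_v)
            if direction == "backward":
                quads = quads[::-1]
            if quads:
                mesh.add_strip([QuadCell(q, 0, j) for j, q in enumerate(quads)])
    if not mesh.strips:
        raise EmptyStripError("no strip survived the area/degeneracy cuts")
    if check_overlap:
        _warn_on_overlap(mesh)
    return mesh


def _warn_on_overlap(mesh: Mesh, n_sample: int = 200, frac_tol: float = 0.02):
    from .transition import CellLocator  # deferred: transition imports mesh

    rng = np.random.default_rng(0)
    loc = CellLocator(mesh)
    coords = mesh.coords_lex()
    picks = rng.choice(len(coords), size=min(n_sample, len(coords)), replace=False)
    bad = 0
    for idx in picks:
        i, j = coords[idx]
        c = mesh.cell(i, j)
        hit = loc.locate(c.centroid)
        if hit is not None and hit != (i, j):
            bad += 1
    if bad > frac_tol * len(picks):
        warnings.warn(
            f"strip overlap: {bad}/{len(picks)} sampled cell centroids located "
            "in a different cell",
            stacklevel=2,
        )


def conductance_seed_line(V_min: float, n_g: int, dg: float) -> np.ndarray:
    """The seed set {(V_min, i*dg) : i = 0..n_g} for the conductance model."""
    return np.array([[V_min, i * dg] for i in range(n_g + 1)])


# ---------------------------------------------------------------------------
# stationary regions, reversal mappings, limit cycles, repair
# ---------------------------------------------------------------------------

def detect_stationary_region(
    model: NeuronModel,
    speed_min: float,
    bbox,
    resolution: int = 60,
    smooth: float = 0.0,
):
    """Find the contiguous region where ||F|| < speed_min and tile it.

    ``bbox`` is (v_lo, w_lo, v_hi, w_hi).  The largest connected sub-speed
    region of a resolution x resolution grid is tiled with quadrilateral
    stationary cells; its boundary is approximated by a periodic cubic
    spline.  Returns (boundary_polygon, cells); both empty when no grid node
    is below ``speed_min``.
    """
    if speed_min < 0:
        raise ValueError("speed_min must be >= 0")
    v_lo, w_lo, v_hi, w_hi = bbox
    vs = np.linspace(v_lo, v_hi, resolution + 1)
    ws = np.linspace(w_lo, w_hi, resolution + 1)
    VV, WW = np.meshgrid(
        0.5 * (vs[:-1] + vs[1:]), 0.5 * (ws[:-1] + ws[1:]), indexing="ij"
    )
    speed = np.linalg.norm(
        model.field(np.stack([VV, WW], axis=-1)), axis=-1
    )
    mask = speed < speed_min
    if not mask.any():
        return np.empty((0, 2)), []
    lab, n = ndimage.label(mask)
    largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
    mask = lab == largest
    cells = []
    ii, jj = np.nonzero(mask)
    for a, b in zip(ii, jj):
        quad = np.array(
            [
                [vs[a], ws[b]],
                [vs[a + 1], ws[b]],
                [vs[a + 1], ws[b + 1]],
                [vs[a], ws[b + 1]],
            ]
        )
        cells.append(QuadCell(quad, 0, len(cells)))
    centers = np.stack([VV[mask], WW[mask]], axis=-1)
    boundary_mask = mask & ~ndimage.binary_erosion(mask)
    bp = np.stack([VV[boundary_mask], WW[boundary_mask]], axis=-1)
    com = centers.mean(axis=0)
    order = np.argsort(np.arctan2(bp[:, 1] - com[1], bp[:, 0] - com[0]))
    bp = bp[order]
    if len(bp) >= 5:
        try:
            tck, _ = splprep([bp[:, 0], bp[:, 1]], s=smooth, per=True, k=3)
            uu = np.linspace(0, 1, 4 * len(bp), endpoint=False)
            bx, by = splev(uu, tck)
            bp = np.stack([bx, by], axis=-1)
        except Exception:  # pragma: no cover - spline failure falls back to raw pts
            pass
    return bp, cells


def build_reversal_mapping(
    mesh: Mesh,
    targets: list[QuadCell] | None = None,
    skip_strips: set[int] | None = None,
) -> MappingTable:
    """Map each strip's first-cell address to its reversal target.

    After a rotation step the mass that has left the spatial end of strip i
    is addressed by cell (i, 0); this table transfers it (fraction 1) to the
    stationary/reversal cell whose centroid is closest to the strip's last
    cell, i.e. to where the flow actually terminates.  Closed (ring) strips
    are skipped.
    """
    targets = mesh.stationary_cells if targets is None else targets
    if not targets:
        raise ValueError("no reversal target cells available")
    skip = (skip_strips or set()) | mesh.closed_strips
    tcent = np.array([t.centroid for t in targets])
    table = MappingTable("reversal")
    for strip in mesh.strips:
        if strip.strip_index in skip:
            continue
        end = strip.cells[-1].centroid
        d = np.linalg.norm(tcent - end, axis=1)
        best = int(np.lexsort((np.arange(len(targets)), d))[0])
        t = targets[best]
        table.entries.append(
            ((strip.strip_index, 0), (t.strip_index, t.cell_index), 1.0)
        )
    return table


def find_limit_cycle(
    model: NeuronModel,
    start,
    t_transient: float = 50.0,
    t_search: float = 50.0,
    dt_sample: float = 1e-3,
    tol: float = 1e-3,
) -> np.ndarray:
    """Locate a stable limit cycle by long integration and first-return search.

    Returns cycle samples at ``dt_sample`` spacing over one period.
    """
    tr = integrate_characteristics(
        model, [start], dt_sample, t_transient, rtol=1e-10
    )[0]
    orbit = integrate_characteristics(
        model, [tr[-1]], dt_sample, t_search, rtol=1e-10
    )[0]
    p0 = orbit[0]
    d = np.linalg.norm(orbit - p0, axis=1)
    scale = d.max()
    away = np.nonzero(d > 0.25 * scale)[0]
    if len(away) == 0:
        raise RuntimeError("trajectory does not leave the start point: no cycle")
    back = np.nonzero(d[away[0]:] < max(tol, 1e-6 * scale))[0]
    if len(back) == 0:
        back = [int(np.argmin(d[away[0]:]))]
    period_idx = away[0] + back[0]
    return orbit[:period_idx]


def build_limit_cycle_ring(
    mesh: Mesh,
    model: NeuronModel,
    epsilon: float,
    cycle: np.ndarray | None = None,
    cycle_start=None,
    gap_factor: float = 5.0,
) -> tuple[Strip, MappingTable]:
    """Tile a band of half-width epsilon around a limit cycle with ring cells.

    The ring is a closed strip whose cells are spaced one mesh time step
    apart along the cycle, so the engine's rotation (mod n) reproduces the
    periodic motion exactly.  Every open strip of ``mesh`` is mapped
    (fraction 1) to the Euclidean-closest ring cell: mass that arrives at
    the end of a strip is deposited on the limit cycle.  The ring strip is
    appended to ``mesh`` (marked closed) and the mapping returned.

    Raises when a strip terminates farther from the ring than
    ``gap_factor`` times the local ring cell size.
    """
    if cycle is None:
        if cycle_start is None:
            raise ValueError("provide either the cycle samples or cycle_start")
        cycle = find_limit_cycle(model, cycle_start, dt_sample=mesh.dt)
    cycle = np.asarray(cycle, float)
    n_ring = len(cycle)
    if n_ring < 3:
        raise ValueError("limit cycle must be sampled at >= 3 points")
    # unit normals from central differences of the cycle tangent
    tang = np.roll(cycle, -1, axis=0) - np.roll(cycle, 1, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    normal = np.stack([-tang[:, 1], tang[:, 0]], axis=-1)
    outer = cycle + epsilon * normal
    inner = cycle - epsilon * normal
    cells = []
    for k in range(n_ring):
        k2 = (k + 1) % n_ring
        quad = np.array([inner[k], inner[k2], outer[k2], outer[k]])
        cells.append(QuadCell(quad, 0, k))
    ring = mesh.add_strip(cells, closed=True)
    rcent = np.array([c.centroid for c in ring.cells])
    table = MappingTable("reversal")
    sizes = np.array([np.sqrt(c.area) for c in ring.cells])
    for strip in mesh.strips:
        if strip.strip_index == ring.strip_index or (
            strip.strip_index in mesh.closed_strips
        ):
            continue
        end = strip.cells[-1].centroid
        d = np.linalg.norm(rcent - end, axis=1)
        best = int(np.lexsort((np.arange(len(ring.cells)), d))[0])
        if d[best] > gap_factor * max(sizes[best], epsilon):
            raise RuntimeError(
                f"strip {strip.strip_index} ends {d[best]:.3g} from the ring; "
                "refine the strips or enlarge epsilon"
            )
        table.entries.append(
            ((strip.strip_index, 0), (ring.strip_index, best), 1.0)
        )
    return ring, table


def repair_degenerate(
    mesh: Mesh, area_min: float = 0.0
) -> tuple[Mesh, MappingTable]:
    """Remove complex or sub-area cells and restore flow continuity.

    Each strip is truncated at its first bad cell; truncated strips get a
    reversal entry from their (new) end to the Euclidean-closest surviving
    cell.  A clean mesh comes back unchanged with an empty table.
    """
    new = Mesh(dt=mesh.dt, labels=mesh.labels)
    new.stationary_cells = list(mesh.stationary_cells)
    truncated: list[int] = []
    for strip in mesh.strips:
        keep: list[QuadCell] = []
        for c in strip.cells:
            try:
                kind = classify_quad(c.vertices)
            except GeometryError:
                kind = "complex"
            if kind == "complex" or c.area < area_min:
                break
            keep.append(c)
        if not keep:
            continue  # strip vanishes entirely
        s = new.add_strip(keep, closed=strip.strip_index in mesh.closed_strips)
        if len(keep) < len(strip.cells):
            truncated.append(s.strip_index)
    table = MappingTable("reversal")
    if truncated:
        cand = [
            c
            for c in new.cells_lex()
        ]
        ccent = np.array([c.centroid for c in cand])
        for si in truncated:
            strip = new.strips[si - 1]
            end = strip.cells[-1].centroid
            d = np.linalg.norm(ccent - end, axis=1)
            order = np.lexsort((np.arange(len(cand)), d))
            best = None
            for o in order:
                c = cand[o]
                if (c.strip_index, c.cell_index) != (si, len(strip) - 1):
                    best = c
                    break
            table.entries.append(
                ((si, 0), (best.strip_index, best.cell_index), 1.0)
            )
    return new, table


# ---------------------------------------------------------------------------
# file formats (line-oriented text; floats at 17 significant digits)
# ---------------------------------------------------------------------------

def write_mesh(mesh: Mesh, path_or_buf) -> None:
    """Serialise a mesh: header (dt, labels), then per-strip cell lines."""
    buf = io.StringIO()
    buf.write(f"dt {FLOAT_FMT % mesh.dt}\n")
    buf.write(f"labels {mesh.labels[0]} {mesh.labels[1]}\n")
    for i in range(0, mesh.n_strips + 1):
        cells = mesh.stationary_cells if i == 0 else mesh.strips[i - 1].cells
        buf.write(f"strip {i}\n")
        for c in cells:
            buf.write(" ".join(FLOAT_FMT % x for x in c.vertices.ravel()) + "\n")
    text = buf.getvalue()
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(text)


def read_mesh(path_or_buf) -> Mesh:
    if hasattr(path_or_buf, "read"):
        lines = path_or_buf.read().splitlines()
    else:
        with open(path_or_buf) as fh:
            lines = fh.read().splitlines()
    dt = None
    labels = ("v", "w")
    strips: dict[int, list[np.ndarray]] = {}
    current = None
    for ln in lines:
        ln = ln.strip()
        if not ln:
            continue
        parts = ln.split()
        if parts[0] == "dt":
            dt = float(parts[1])
        elif parts[0] == "labels":
            labels = (parts[1], parts[2])
        elif parts[0] == "strip":
            current = int(parts[1])
            strips.setdefault(current, [])
        else:
            if current is None:
                raise ValueError("cell line before any 'strip' header")
            vals = np.array([float(x) for x in parts]).reshape(4, 2)
            strips[current].append(vals)
    if dt is None:
        raise ValueError("mesh file lacks a dt header")
    mesh = Mesh(dt=dt, labels=labels)
    for j, q in enumerate(strips.get(0, [])):
        mesh.add_stationary_cell(q)
    for i in sorted(k for k in strips if k > 0):
        mesh.add_strip([QuadCell(q, i, j) for j, q in enumerate(strips[i])])
    return mesh


_MAP_EXT = {"reversal": ".rev", "reset": ".res"}


def write_mapping(table: MappingTable, path_or_buf) -> None:
    """One line per entry: ``i,j p,q fraction``."""
    buf = io.StringIO()
    for (i, j), (p, q), frac in table.entries:
        buf.write(f"{i},{j} {p},{q} {FLOAT_FMT % frac}\n")
    text = buf.getvalue()
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(text)


def read_mapping(path_or_buf, kind: str | None = None) -> MappingTable:
    if hasattr(path_or_buf, "read"):
        lines = path_or_buf.read().splitlines()
        if kind is None:
            raise ValueError("kind required when reading from a buffer")
    else:
        path = str(path_or_buf)
        if kind is None:
            for k, ext in _MAP_EXT.items():
                if path.endswith(ext):
                    kind = k
            if kind is None:
                raise ValueError(f"cannot infer mapping kind from {path}")
        with open(path) as fh:
            lines = fh.read().splitlines()
    table = MappingTable(kind)
    for ln in lines:
        ln = ln.strip()
        if not ln:
            continue
        src, tgt, frac = ln.split()
        i, j = (int(x) for x in src.split(","))
        p, q = (int(x) for x in tgt.split(","))
        table.entries.append(((i, j), (p, q), float(frac)))
    return table
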