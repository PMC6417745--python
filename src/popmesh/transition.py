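"""Monte-Carlo transition matrices for Poisson synaptic jumps.

An input spike displaces a neuron instantaneously by a jump vector h in
state space.  On a mesh, the mass leaving cell (i, j) reappears spread over
the cells covered by the translated cell — the *displacement set*
C_h(i, j) with overlap fractions alpha.  The fractions are estimated by
Monte Carlo: N_point points are sampled uniformly in the origin cell,
translated by h, and located in the mesh; alpha_{p,q} = n_{(p,q)}/N_point.
The collection of all displacement sets is the (row-stochastic, sparse)
transition matrix that generates the noise part of the dynamics.

Translated points that fall in gaps of the mesh are reassigned — via
user-supplied fiducial polygons or by the closest cell along the projection
of the jump direction — so that no probability mass is lost.  Points that
end up above the threshold potential are attributed to the closest
threshold cell, ruling out transitions into supra-threshold cells.

Point location honours the first-match-wins rule in (strip, cell)
lexicographic order; a bounding-box candidate filter accelerates the search
without changing which cell wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import sparse

from .geometry import ComplexCellError, classify_quad, triangulate_quad
from .mesh import FLOAT_FMT, MappingTable, Mesh

__all__ = [
    "CellLocator",
    "FiducialCell",
    "DisplacementSet",
    "TransitionMatrix",
    "UnresolvedEventError",
    "locate",
    "compute_displacement_set",
    "reassign_lost_event",
    "build_transition_matrix",
    "build_threshold_reset_mapping",
    "threshold_cells",
    "reset_cells",
    "write_matrix",
    "read_matrix",
]


class UnresolvedEventError(RuntimeError):
    """A translated event could not be attributed to any mesh cell."""


@dataclass
class FiducialCell:
    """A helper polygon covering a known gap in the mesh.

    ``associated`` holds the flat indices of mesh cells with at least one
    vertex inside the polygon; lost events inside the fiducial are
    reassigned to the associated cell closest along the jump projection.
    """

    vertices: np.ndarray
    associated: list[int] = dc_field(default_factory=list)

    def attach(self, locator: "CellLocator") -> None:
        verts = locator.verts.reshape(-1, 2)
        from .geometry import contains_many

        inside = contains_many(self.vertices, verts).reshape(-1, 4).any(axis=1)
        self.associated = [int(i) for i in np.nonzero(inside)[0]]


@dataclass
class DisplacementSet:
    """Monte-Carlo estimate of where one cell's mass lands after a jump."""

    origin: tuple[int, int]
    jump: np.ndarray
    counts: dict[tuple[int, int], int]
    n_points: int
    n_lost_raw: int

    @property
    def entries(self) -> dict[tuple[int, int], float]:
        return {k: c / self.n_points for k, c in self.counts.items()}


class CellLocator:
    """Point-in-mesh location with first-match-wins lexicographic search.

    Every simple cell is split into two triangles; membership is a
    half-plane test against the triangles' inward edge normals, vectorised
    over points.  The linear search of the reference method is preserved
    semantically: cells are tested in (strip, cell) order and the first
    containing cell wins; a bounding-box pre-filter only skips cells that
    cannot contain a point.
    """

    def __init__(self, mesh: Mesh):
        self.mesh = mesh
        self.coords = mesh.coords_lex()
        cells = list(mesh.cells_lex())
        if not cells:
            raise ValueError("empty mesh")
        self.verts = np.stack([c.vertices for c in cells])  # (N, 4, 2)
        self.centroids = np.stack([c.centroid for c in cells])
        self.areas = np.array([c.area for c in cells])
        self.lo = self.verts.min(axis=1)
        self.hi = self.verts.max(axis=1)
        tris = []
        for c in cells:
            kind = classify_quad(c.vertices)
            if kind == "complex":
                raise ComplexCellError(
                    f"complex cell {(c.strip_index, c.cell_index)} in mesh; "
                    "run repair_degenerate first"
                )
            t1, t2 = triangulate_quad(c.vertices)
            if np.linalg.det(np.array([t1[1] - t1[0], t1[2] - t1[0]])) < 0:
                t1 = t1[::-1]
            if np.linalg.det(np.array([t2[1] - t2[0], t2[2] - t2[0]])) < 0:
                t2 = t2[::-1]
            tris.append([t1, t2])
        tri = np.array(tris)  # (N, 2, 3, 2) CCW triangles
        self.tri_a = tri  # anchors: vertex k of each triangle edge
        edge = np.roll(tri, -1, axis=2) - tri  # (N, 2, 3, 2) edge vectors
        # inward normal of CCW edge (ex, ey) is (-ey, ex)
        self.tri_n = np.stack([-edge[..., 1], edge[..., 0]], axis=-1)
        scale = np.maximum(
            (self.hi - self.lo).max(axis=1), 1e-300
        )
        self.tol = 1e-12 * scale * scale
        # triangle areas for fast in-cell sampling
        t = self.tri_a
        self.tri_areas = 0.5 * np.abs(
            (t[:, :, 1, 0] - t[:, :, 0, 0]) * (t[:, :, 2, 1] - t[:, :, 0, 1])
            - (t[:, :, 2, 0] - t[:, :, 0, 0]) * (t[:, :, 1, 1] - t[:, :, 0, 1])
        )
        self._n = len(cells)

    def sample_in_cell(self, ci: int, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform points in cell ``ci`` using the precomputed triangulation."""
        from .geometry import _sample_triangle

        a1, a2 = self.tri_areas[ci]
        n1 = int(rng.binomial(n, a1 / (a1 + a2)))
        parts = []
        if n1 > 0:
            parts.append(_sample_triangle(self.tri_a[ci, 0], n1, rng))
        if n - n1 > 0:
            parts.append(_sample_triangle(self.tri_a[ci, 1], n - n1, rng))
        return np.concatenate(parts, axis=0)

    def __len__(self) -> int:
        return self._n

    def contains_points(self, ci: int, pts: np.ndarray) -> np.ndarray:
        """Closed membership of many points in cell ``ci``."""
        d = np.einsum(
            "tkd,ptkd->ptk",
            self.tri_n[ci],
            pts[:, None, None, :] - self.tri_a[ci][None],
        )
        return (d >= -self.tol[ci]).all(axis=2).any(axis=1)

    def candidate_ids(self, pts_lo, pts_hi) -> np.ndarray:
        """Cells whose bbox intersects the query bbox, in lex order."""
        m = (
            (self.lo[:, 0] <= pts_hi[0])
            & (self.hi[:, 0] >= pts_lo[0])
            & (self.lo[:, 1] <= pts_hi[1])
            & (self.hi[:, 1] >= pts_lo[1])
        )
        return np.nonzero(m)[0]

    def assign(self, pts: np.ndarray) -> np.ndarray:
        """First containing cell (flat id) per point, -1 when outside."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        out = np.full(len(pts), -1, dtype=np.int64)
        if len(pts) == 0:
            return out
        cand = self.candidate_ids(pts.min(axis=0), pts.max(axis=0))
        open_idx = np.arange(len(pts))
        for ci in cand:
            if len(open_idx) == 0:
                break
            sub = pts[open_idx]
            inb = (
                (sub[:, 0] >= self.lo[ci, 0])
                & (sub[:, 0] <= self.hi[ci, 0])
                & (sub[:, 1] >= self.lo[ci, 1])
                & (sub[:, 1] <= self.hi[ci, 1])
            )
            if not inb.any():
                continue
            pos = np.nonzero(inb)[0]
            hit = self.contains_points(ci, pts[open_idx[pos]])
            if hit.any():
                out[open_idx[pos[hit]]] = ci
                keep = np.ones(len(open_idx), dtype=bool)
                keep[pos[hit]] = False
                open_idx = open_idx[keep]
        return out

    def locate(self, p) -> tuple[int, int] | None:
        """Grid coordinates of the first cell containing ``p`` (or None)."""
        flat = int(self.assign(np.asarray(p, float)[None, :])[0])
        return None if flat < 0 else self.coords[flat]


def locate(mesh: Mesh, p) -> tuple[int, int] | None:
    """One-shot point location (builds a locator; prefer CellLocator)."""
    return CellLocator(mesh).locate(p)


def threshold_cells(mesh: Mesh, threshold_v: float) -> list[int]:
    """Flat ids of cells with a vertex below threshold and one on/above it."""
    out = []
    for flat, c in enumerate(mesh.cells_lex()):
        v = c.vertices[:, 0]
        if v.min() < threshold_v <= v.max():
            out.append(flat)
    return out


def reset_cells(mesh: Mesh, reset_v: float) -> list[int]:
    """Flat ids of cells whose v-extent contains the reset potential."""
    out = []
    for flat, c in enumerate(mesh.cells_lex()):
        v = c.vertices[:, 0]
        if v.min() <= reset_v <= v.max():
            out.append(flat)
    return out


def _jump_frame(h: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = np.linalg.norm(h)
    if n == 0:
        return np.array([1.0, 0.0]), np.array([0.0, 1.0])
    u = h / n
    return u, np.array([-u[1], u[0]])


def reassign_lost_event(
    p_translated,
    jump,
    locator: CellLocator,
    fiducials: list[FiducialCell] | None = None,
    cutoff_diameters: float = 5.0,
) -> tuple[int, int]:
    """Attribute one off-mesh event to the closest cell along the jump.

    Fiducial polygons take precedence: an event inside one is assigned to
    the fiducial's associated cell closest along the jump-direction
    projection.  Otherwise the closest mesh cell by jump-projected distance
    wins, provided the event lies within ``cutoff_diameters`` local cell
    diameters of that cell; beyond the cutoff the event is unresolvable.
    """
    flat = _reassign_many(
        np.asarray(p_translated, float)[None, :],
        np.asarray(jump, float),
        locator,
        fiducials,
        cutoff_diameters,
    )[0]
    return locator.coords[int(flat)]


def _bbox_gaps(locator: CellLocator, cand: np.ndarray, pts: np.ndarray,
               u_par: np.ndarray, u_perp: np.ndarray):
    """Componentwise gap from each point to each candidate cell's bbox,
    decomposed along and perpendicular to the jump direction."""
    lo = locator.lo[cand][None, :, :]
    hi = locator.hi[cand][None, :, :]
    p = pts[:, None, :]
    gap = np.maximum(np.maximum(lo - p, p - hi), 0.0)
    d_par = np.abs(gap @ u_par)
    d_perp = np.abs(gap @ u_perp)
    return d_par, d_perp


def _pick_nearest_along_jump(locator, cand, pts, u_par, u_perp, cutoff=None):
    """Per point: candidate minimising (perp gap, parallel gap, lex id).

    A point is resolvable when the perpendicular gap is (near) zero for some
    candidate — the jump line would sweep through that cell — and the
    parallel gap stays below ``cutoff`` local cell extents along the jump.
    """
    d_par, d_perp = _bbox_gaps(locator, cand, pts, u_par, u_perp)
    ext = locator.hi[cand] - locator.lo[cand]
    scale = max(float(ext.max()), 1e-300)
    if cutoff is not None:
        ext_par = np.abs(ext @ np.abs(u_par))
        ext_perp = np.abs(ext @ np.abs(u_perp))
        ok = (d_par <= cutoff * ext_par[None, :]) & (
            d_perp <= cutoff * ext_perp[None, :]
        )
    else:
        ok = np.ones_like(d_par, dtype=bool)
    # composite key: perpendicular gap dominates, then the parallel gap,
    # then the lexicographic cell id as the deterministic tie-break
    score = (
        d_perp * 1e8
        + d_par
        + (cand[None, :] / max(len(locator), 1)) * (1e-9 * scale)
    )
    score[~ok] = np.inf
    best = np.argmin(score, axis=1)
    resolved = np.isfinite(score[np.arange(len(pts)), best])
    return cand[best], resolved


def _reassign_many(
    pts: np.ndarray,
    jump: np.ndarray,
    locator: CellLocator,
    fiducials: list[FiducialCell] | None,
    cutoff_diameters: float,
) -> np.ndarray:
    u_par, u_perp = _jump_frame(jump)
    out = np.full(len(pts), -1, dtype=np.int64)
    todo = np.ones(len(pts), dtype=bool)
    if fiducials:
        from .geometry import contains_many

        for fid in fiducials:
            if not fid.associated:
                fid.attach(locator)
            if not fid.associated or not todo.any():
                continue
            idx = np.nonzero(todo)[0]
            inside = contains_many(fid.vertices, pts[idx])
            if not inside.any():
                continue
            hit = idx[inside]
            cand = np.array(fid.associated)
            best, _ = _pick_nearest_along_jump(
                locator, cand, pts[hit], u_par, u_perp
            )
            out[hit] = best
            todo[hit] = False
    if todo.any():
        idx = np.nonzero(todo)[0]
        sub = pts[idx]
        # a cell can only capture events within cutoff x its own extent, so
        # expand every cell bbox by that much and intersect with the points
        ext = locator.hi - locator.lo
        lo_e = locator.lo - cutoff_diameters * ext
        hi_e = locator.hi + cutoff_diameters * ext
        p_lo = sub.min(axis=0)
        p_hi = sub.max(axis=0)
        cand = np.nonzero(
            (lo_e[:, 0] <= p_hi[0])
            & (hi_e[:, 0] >= p_lo[0])
            & (lo_e[:, 1] <= p_hi[1])
            & (hi_e[:, 1] >= p_lo[1])
        )[0]
        if len(cand) == 0:
            raise UnresolvedEventError(
                f"{len(idx)} events beyond the reassignment cutoff of any cell"
            )
        best, resolved = _pick_nearest_along_jump(
            locator, cand, sub, u_par, u_perp, cutoff=cutoff_diameters
        )
        if not resolved.all():
            p = sub[~resolved][0]
            raise UnresolvedEventError(
                f"{int((~resolved).sum())} events unresolvable; first at "
                f"({p[0]:.6g}, {p[1]:.6g}) with jump ({jump[0]:.6g}, {jump[1]:.6g})"
            )
        out[idx] = best
    return out


def compute_displacement_set(
    mesh_or_locator,
    origin: tuple[int, int],
    h,
    n_point: int,
    rng: np.random.Generator,
    fiducials: list[FiducialCell] | None = None,
    threshold_v: float | None = None,
    threshold_set: list[int] | None = None,
    cutoff_diameters: float = 5.0,
) -> DisplacementSet:
    """Monte-Carlo displacement set of one origin cell for jump ``h``."""
    loc = (
        mesh_or_locator
        if isinstance(mesh_or_locator, CellLocator)
        else CellLocator(mesh_or_locator)
    )
    if n_point < 1:
        raise ValueError("n_point must be >= 1")
    h = np.asarray(h, dtype=float)
    i, j = origin
    flat_origin = loc.mesh.flat_index(i, j)
    pts = loc.sample_in_cell(flat_origin, n_point, rng) + h
    flat = loc.assign(pts)
    n_lost_raw = int((flat < 0).sum())
    if threshold_v is not None:
        if threshold_set is None:
            threshold_set = threshold_cells(loc.mesh, threshold_v)
        above = pts[:, 0] > threshold_v
        if above.any():
            if not threshold_set:
                raise UnresolvedEventError(
                    "events above threshold but the mesh has no threshold cells"
                )
            tc = np.array(threshold_set)
            d = np.linalg.norm(
                loc.centroids[tc][None, :, :] - pts[above][:, None, :], axis=2
            )
            flat[above] = tc[np.argmin(d, axis=1)]
    lost = flat < 0
    if lost.any():
        flat[lost] = _reassign_many(
            pts[lost], h, loc, fiducials, cutoff_diameters
        )
    counts_arr = np.bincount(flat, minlength=len(loc))
    counts = {
        loc.coords[k]: int(c) for k, c in enumerate(counts_arr) if c > 0
    }
    return DisplacementSet(
        origin=origin, jump=h, counts=counts, n_points=n_point,
        n_lost_raw=n_lost_raw,
    )


@dataclass
class TransitionMatrix:
    """Sparse row-stochastic jump matrix: one displacement set per cell.

    ``counts`` is an (N, N) integer CSR matrix of Monte-Carlo hit counts in
    flat lexicographic cell order (origin rows, destination columns); alpha
    values are exact rationals count/n_point so every row sums to exactly 1.
    """

    mesh_id: str
    jump_label: str
    n_point: int
    seed: int
    counts: sparse.csr_matrix
    coords: list[tuple[int, int]]

    def alpha(self) -> sparse.csr_matrix:
        return self.counts.astype(float) / self.n_point

    def generator_t(self) -> sparse.csr_matrix:
        """alpha^T - I: applied to static-ordered mass, times rate nu."""
        a = self.alpha()
        return (a.T - sparse.identity(a.shape[0], format="csr")).tocsr()

    def row_sums(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel() / self.n_point

    def displacement_set(self, origin: tuple[int, int]) -> dict:
        r = self.coords.index(origin)
        row = self.counts.getrow(r)
        return {
            self.coords[c]: int(v) / self.n_point
            for c, v in zip(row.indices, row.data)
        }


def build_transition_matrix(
    mesh: Mesh,
    jump,
    n_point: int = 10_000,
    seed: int = 0,
    fiducials: list[FiducialCell] | None = None,
    threshold_v: float | None = None,
    locator: CellLocator | None = None,
    cutoff_diameters: float = 5.0,
    jump_label: str | None = None,
    mesh_id: str = "mesh",
) -> TransitionMatrix:
    """Build the full transition matrix for a fixed or state-dependent jump.

    ``jump`` is either a 2-vector (fixed efficacy) or a callable mapping an
    (N, 2) array of cell centroids to (N, 2) per-cell jump vectors (e.g. the
    Tsodyks-Markram rule).  Deterministic for a given seed.
    """
    loc = locator or CellLocator(mesh)
    rng = np.random.default_rng(seed)
    coords = loc.coords
    n = len(coords)
    if callable(jump):
        jumps = np.asarray(jump(loc.centroids), dtype=float)
        if jump_label is None:
            jump_label = "rule"
    else:
        jumps = np.broadcast_to(np.asarray(jump, dtype=float), (n, 2))
        if jump_label is None:
            jump_label = f"{FLOAT_FMT % jumps[0, 0]} {FLOAT_FMT % jumps[0, 1]}"
    thr_set = (
        threshold_cells(mesh, threshold_v) if threshold_v is not None else None
    )
    rows, cols, vals = [], [], []
    for r, origin in enumerate(coords):
        try:
            ds = compute_displacement_set(
                loc, origin, jumps[r], n_point, rng,
                fiducials=fiducials, threshold_v=threshold_v,
                threshold_set=thr_set, cutoff_diameters=cutoff_diameters,
            )
        except UnresolvedEventError as exc:
            raise UnresolvedEventError(
                f"cell {origin}: {exc}"
            ) from exc
        for tgt, c in ds.counts.items():
            rows.append(r)
            cols.append(mesh.flat_index(*tgt))
            vals.append(c)
    counts = sparse.csr_matrix(
        (np.asarray(vals, dtype=np.int64), (rows, cols)), shape=(n, n)
    )
    return TransitionMatrix(
        mesh_id=mesh_id, jump_label=jump_label, n_point=n_point, seed=seed,
        counts=counts, coords=coords,
    )


def build_threshold_reset_mapping(
    mesh: Mesh,
    threshold_v: float,
    reset_v: float,
    w_increment: float = 0.0,
    n_point: int = 10_000,
    seed: int = 0,
    locator: CellLocator | None = None,
) -> MappingTable:
    """Map threshold-straddling cells to the reset region.

    With no adaptation jump (``w_increment`` = 0) each threshold cell maps,
    fraction 1, to the reset cell closest in w.  With a jump b, the matched
    reset cell is translated by (0, b) and its Monte-Carlo displacement set
    supplies the fractions, exactly as for a transition matrix.
    """
    loc = locator or CellLocator(mesh)
    thr = threshold_cells(mesh, threshold_v)
    res = reset_cells(mesh, reset_v)
    if not res:
        raise ValueError(f"no cell contains the reset potential {reset_v}")
    if not thr:
        raise ValueError(f"no cell straddles the threshold potential {threshold_v}")
    rng = np.random.default_rng(seed)
    res_arr = np.array(res)
    res_w = loc.centroids[res_arr, 1]
    table = MappingTable("reset")
    # reset targets must themselves stay below threshold
    ds_cache: dict[int, dict] = {}
    for t in thr:
        w_t = loc.centroids[t, 1]
        dw = np.abs(res_w - w_t)
        best = int(res_arr[np.lexsort((res_arr, dw))[0]])
        src = loc.coords[t]
        if w_increment == 0.0:
            table.entries.append((src, loc.coords[best], 1.0))
        else:
            if best not in ds_cache:
                ds = compute_displacement_set(
                    loc, loc.coords[best], (0.0, w_increment), n_point, rng,
                    threshold_v=threshold_v,
                )
                ds_cache[best] = ds.entries
            for tgt, frac in sorted(ds_cache[best].items()):
                table.entries.append((src, tgt, frac))
    return table


# ---------------------------------------------------------------------------
# matrix file format
# ---------------------------------------------------------------------------

def write_matrix(tm: TransitionMatrix, path_or_buf) -> None:
    """Serialise with alphas as exact rationals ``count/N_point``."""
    import io

    buf = io.StringIO()
    buf.write(f"mesh {tm.mesh_id}\n")
    buf.write(f"jump {tm.jump_label}\n")
    buf.write(f"npoint {tm.n_point}\n")
    buf.write(f"seed {tm.seed}\n")
    coo = tm.counts.tocoo()
    order = np.lexsort((coo.col, coo.row))
    for r, c, v in zip(coo.row[order], coo.col[order], coo.data[order]):
        (i, j), (p, q) = tm.coords[r], tm.coords[c]
        buf.write(f"{i},{j} {p},{q} {int(v)}/{tm.n_point}\n")
    text = buf.getvalue()
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(text)


def read_matrix(path_or_buf, mesh: Mesh) -> TransitionMatrix:
    if hasattr(path_or_buf, "read"):
        lines = path_or_buf.read().splitlines()
    else:
        with open(path_or_buf) as fh:
            lines = fh.read().splitlines()
    header = {"mesh": "mesh", "jump": "", "npoint": "0", "seed": "0"}
    rows, cols, vals = [], [], []
    n_point = None
    for ln in lines:
        ln = ln.strip()
        if not ln:
            continue
        key = ln.split(None, 1)[0]
        if key in header:
            header[key] = ln.split(None, 1)[1]
            if key == "npoint":
                n_point = int(header[key])
            continue
        src, tgt, frac = ln.split()
        i, j = (int(x) for x in src.split(","))
        p, q = (int(x) for x in tgt.split(","))
        num, den = frac.split("/")
        if n_point is None:
            n_point = int(den)
        rows.append(mesh.flat_index(i, j))
        cols.append(mesh.flat_index(p, q))
        vals.append(int(num))
    n = mesh.n_cells
    counts = sparse.csr_matrix(
        (np.asarray(vals, dtype=np.int64), (rows, cols)), shape=(n, n)
    )
    return TransitionMatrix(
        mesh_id=header["mesh"], jump_label=header["jump"],
        n_point=int(n_point or 0), seed=int(header["seed"]),
        counts=counts, coords=mesh.coords_lex(),
    )
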