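"""Mesh construction: strips from characteristics, mappings, file formats."""

import io

import numpy as np
import pytest

import popmesh as pm
from popmesh.geometry import QuadCell
from popmesh.mesh import (
    EmptyStripError,
    MappingTable,
    Mesh,
    build_limit_cycle_ring,
    build_mesh,
    build_reversal_mapping,
    build_strip,
    detect_stationary_region,
    read_mapping,
    read_mesh,
    repair_degenerate,
    write_mapping,
    write_mesh,
)
from popmesh.models import NeuronModel, get_model, qif_field


class TestBuildStrip:
    def test_lif_cells_shrink_geometrically(self):
        """LIF characteristics decay as exp(-t/tau): cell k spans
        [e^{-(k+1)dt/tau}, e^{-k dt/tau}] x the seed interval."""
        model = get_model("lif", tau=0.05)
        dt = 1e-4
        strip = build_strip(
            model, (1.0, 0.0), (1.0, 0.02), dt, t_end=0.01, area_min=0.0
        )
        shrink = np.exp(-dt / 0.05)
        for k, c in enumerate(strip.cells[:50]):
            v = np.sort(np.unique(np.round(c.vertices[:, 0], 15)))
            assert v[-1] == pytest.approx(np.exp(-k * dt / 0.05), rel=1e-9)
            assert v[0] == pytest.approx(np.exp(-(k + 1) * dt / 0.05), rel=1e-9)
        widths = np.array(
            [c.vertices[:, 0].max() - c.vertices[:, 0].min()
             for c in strip.cells[:50]]
        )
        assert np.allclose(widths[1:] / widths[:-1], shrink, rtol=1e-8)

    def test_identical_seeds_rejected(self):
        model = get_model("lif")
        with pytest.raises(ValueError):
            build_strip(model, (1.0, 0.0), (1.0, 0.0), 1e-4, 0.01)

    def test_zero_width_strip_is_empty(self):
        # seeds on the same characteristic: every cell is degenerate
        model = get_model("lif", tau=0.05)
        v2 = 1.0 * np.exp(-1e-4 / 0.05)
        with pytest.raises(EmptyStripError):
            build_strip(model, (1.0, 0.0), (v2, 0.0), 1e-4, 0.01, area_min=1e-12)


class TestBuildMesh:
    def test_lif_two_strips(self, lif_fx):
        assert lif_fx["mesh"].n_strips == 2

    def test_bursting_qif_single_strip(self, qif_fx):
        assert qif_fx["mesh"].n_strips == 1

    def test_qif_with_fixed_points_three_strips(self):
        """A QIF with F = V^2 - 1 has a stable point at -1 and an unstable
        one at +1, splitting the potential axis into three strips."""
        model = NeuronModel(
            name="qif_excitable",
            field=lambda p: qif_field(p, tau=0.01, I_c=-1.0),
            jump_dimension="v",
        )
        mesh = build_mesh(
            model,
            [
                [(-10.0, 0.0), (-10.0, 1.0)],   # -> stable point at -1
                [(0.9, 0.0), (0.9, 1.0)],       # backflow -1 < V < 1
                [(1.1, 0.0), (1.1, 1.0)],       # runaway V > 1
            ],
            dt=1e-4,
            t_end=0.05,
            area_min=1e-7,
            threshold_v=10.0,
            v_ceiling=11.0,
        )
        assert mesh.n_strips == 3

    def test_single_strip_from_two_seeds(self):
        model = get_model("lif", tau=0.05)
        mesh = build_mesh(
            model, [[(1.0, 0.0), (1.0, 1.0)]], 1e-4, 0.01, area_min=0.0
        )
        assert mesh.n_strips == 1

    def test_lif_meshed_extent_matches_seed_interval(self, lif_fx):
        """The mesh plus the stationary bin tile [-1, 1) without gaps."""
        mesh = lif_fx["mesh"]
        edges = []
        for c in mesh.cells_lex():
            v = c.vertices[:, 0]
            edges.append((v.min(), v.max()))
        edges.sort()
        # contiguous cover: each interval starts where some interval ended
        total = sum(b - a for a, b in edges)
        assert total == pytest.approx(2.0, abs=1e-9)
        assert min(a for a, _ in edges) == pytest.approx(-1.0, abs=1e-12)
        assert max(b for _, b in edges) == pytest.approx(1.0, abs=1e-12)


class TestMeshInvariants:
    def test_cells_simple_and_shared_edges(self, lif_fx, tm_fx):
        for fx in (lif_fx, tm_fx):
            mesh = fx["mesh"]
            for strip in mesh.strips:
                for c in strip.cells:
                    assert c.classify() in ("convex_simple", "concave_simple")
                for a, b in zip(strip.cells[:-1], strip.cells[1:]):
                    # leading edge of cell k is the trailing edge of cell k+1
                    va = {tuple(v) for v in a.vertices}
                    vb = {tuple(v) for v in b.vertices}
                    assert len(va & vb) >= 2


class TestStationaryRegion:
    def test_lif_region_surrounds_origin(self):
        model = get_model("lif", tau=0.05)
        boundary, cells = detect_stationary_region(
            model, speed_min=1.0, bbox=(-1, 0, 1, 1), resolution=40
        )
        assert cells
        vs = np.array([c.centroid[0] for c in cells])
        assert np.abs(vs).max() < 0.1  # only the neighbourhood of V = 0

    def test_zero_speed_min_empty(self):
        model = get_model("lif")
        boundary, cells = detect_stationary_region(
            model, 0.0, (-1, 0, 1, 1), resolution=10
        )
        assert len(cells) == 0 and len(boundary) == 0

    def test_fhn_slow_region_near_central_branch(self):
        # the slow (canard) region sits around the unstable fixed point
        # (-0.80, -0.13) and the central cubic branch
        model = get_model("fhn", I=0.5)
        boundary, cells = detect_stationary_region(
            model, speed_min=0.1, bbox=(-1.1, -0.7, 0.5, 0.9), resolution=24
        )
        assert cells
        cen = np.array([c.centroid for c in cells]).mean(axis=0)
        assert -1.0 < cen[0] < 0.5 and -0.7 < cen[1] < 0.9
        assert len(boundary) > 0


class TestLimitCycleRing:
    def test_circle_ring_geometry(self, ring_fx):
        ring = ring_fx["ring"]
        assert len(ring.cells) >= 3
        radii = np.linalg.norm(
            np.array([c.centroid for c in ring.cells]), axis=1
        )
        assert np.abs(radii.mean() - 1.0) < ring_fx["epsilon"]

    def test_every_open_strip_mapped_to_ring(self, ring_fx):
        mesh = ring_fx["mesh"]
        ring = ring_fx["ring"]
        mapped = {src[0] for src, _, _ in ring_fx["reversal"].entries}
        open_strips = {
            s.strip_index for s in mesh.strips
            if s.strip_index != ring.strip_index
        }
        assert mapped == open_strips
        for _, tgt, frac in ring_fx["reversal"].entries:
            assert tgt[0] == ring.strip_index
            assert frac == 1.0

    def test_wide_gap_raises(self):
        from popmesh.fixtures import _circle_model

        model = _circle_model()
        mesh = Mesh(dt=0.1)
        far = QuadCell(
            np.array([[3.0, 0.0], [3.1, 0.0], [3.1, 0.1], [3.0, 0.1]]), 0, 0
        )
        mesh.add_strip([far])
        theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        cycle = np.stack([np.cos(theta), np.sin(theta)], axis=-1)
        with pytest.raises(RuntimeError, match="refine"):
            build_limit_cycle_ring(
                mesh, model, 0.01, cycle=cycle, gap_factor=2.0
            )


class TestReversalMapping:
    def test_all_strip_starts_mapped_to_single_bin(self, toy_fx):
        table = toy_fx["reversal"]
        assert sorted(src for src, _, _ in table.entries) == [(1, 0), (2, 0)]
        assert all(tgt == (0, 0) for _, tgt, _ in table.entries)

    def test_cond_strips_end_at_equilibrium_bin(self, cond_runs):
        fx, _ = cond_runs["free"]
        mesh = fx["mesh"]
        bin_cent = mesh.stationary_cells[0].centroid
        assert bin_cent[0] == pytest.approx(-65.0, abs=0.5)
        for src, tgt, frac in fx["reversal"].entries:
            assert tgt == (0, 0) and frac == 1.0

    def test_no_targets_is_an_error(self):
        mesh = Mesh(dt=1e-3)
        mesh.add_strip(
            [QuadCell(np.array([[0, 0], [1, 0], [1, 1], [0, 1.0]]), 0, 0)]
        )
        with pytest.raises(ValueError):
            build_reversal_mapping(mesh)


class TestRepairDegenerate:
    def _mesh_with_bowtie(self):
        mesh = Mesh(dt=1e-3)
        good = [
            np.array([[k, 0.0], [k + 1, 0.0], [k + 1, 1.0], [k, 1.0]])
            for k in range(3)
        ]
        bow = np.array([[3.0, 0.0], [4.0, 1.0], [4.0, 0.0], [3.0, 1.0]])
        cells = [QuadCell(q, 0, j) for j, q in enumerate(good)]
        bad = QuadCell.__new__(QuadCell)  # bypass orientation check
        bad.vertices = bow
        bad.strip_index, bad.cell_index = 1, 3
        bad.area = 0.0
        cells.append(bad)
        mesh.add_strip(cells)
        return mesh

    def test_bowtie_removed_and_predecessor_remapped(self):
        mesh = self._mesh_with_bowtie()
        fixed, table = repair_degenerate(mesh)
        assert len(fixed.strips[0]) == 3
        assert table.entries and table.entries[0][0] == (1, 0)

    def test_clean_mesh_unchanged(self, toy_fx):
        mesh = toy_fx["mesh"]
        fixed, table = repair_degenerate(mesh)
        assert table.entries == []
        assert fixed.n_cells == mesh.n_cells

    def test_small_area_cells_truncated(self):
        mesh = Mesh(dt=1e-3)
        quads = [
            np.array([[k, 0.0], [k + 1, 0.0], [k + 1, 1.0], [k, 1.0]])
            for k in range(2)
        ]
        quads.append(
            np.array([[2.0, 0.0], [2.001, 0.0], [2.001, 1.0], [2.0, 1.0]])
        )
        mesh.add_strip([QuadCell(q, 0, j) for j, q in enumerate(quads)])
        fixed, table = repair_degenerate(mesh, area_min=0.01)
        assert len(fixed.strips[0]) == 2
        assert len(table.entries) == 1


class TestFileFormats:
    def test_mesh_round_trip_bit_exact(self, lif_fx):
        mesh = lif_fx["mesh"]
        buf = io.StringIO()
        write_mesh(mesh, buf)
        text1 = buf.getvalue()
        mesh2 = read_mesh(io.StringIO(text1))
        buf2 = io.StringIO()
        write_mesh(mesh2, buf2)
        assert buf2.getvalue() == text1
        assert mesh2.dt == mesh.dt
        for c1, c2 in zip(mesh.cells_lex(), mesh2.cells_lex()):
            assert np.array_equal(c1.vertices, c2.vertices)

    def test_mapping_round_trip(self, tmp_path):
        table = MappingTable(
            "reversal", [((1, 0), (0, 0), 1.0), ((2, 0), (0, 1), 0.5),
                         ((2, 0), (0, 0), 0.5)]
        )
        p = tmp_path / "m.rev"
        write_mapping(table, p)
        back = read_mapping(p)
        assert back.kind == "reversal"
        assert back.entries == table.entries

    def test_mapping_validation(self, toy_fx):
        bad = MappingTable("reversal", [((1, 0), (0, 0), 0.7)])
        with pytest.raises(ValueError, match="sum"):
            bad.validate(toy_fx["mesh"])
        missing = MappingTable("reversal", [((1, 0), (9, 0), 1.0)])
        with pytest.raises(ValueError, match="target"):
            missing.validate(toy_fx["mesh"])
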