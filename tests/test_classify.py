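import numpy as np
import pytest

from septumfem import RunConfig, run_pipeline
from septumfem.classify import (
    classify_mode,
    classify_modeset,
    count_sign_regions,
    modal_von_mises,
    out_of_plane_fraction,
    type_summary,
)
from septumfem.fem_core import Material, TipSpring, assemble_system
from septumfem.geometry import landmark_regions
from septumfem.modal import Mode, ModeSet, merge_and_sort, solve_bending_modes, solve_membrane_modes
from septumfem.synthetic import rectangular_plate_fixture


@pytest.fixture(scope="module")
def septum_system(mesh, material):
    return assemble_system(mesh, material, TipSpring(20e3))


@pytest.fixture(scope="module")
def septum_modes(septum_system):
    b = solve_bending_modes(septum_system, None, 10)
    m = solve_membrane_modes(septum_system, 10)
    return merge_and_sort(b, m, 10)


class TestOutOfPlaneFraction:
    def test_pure_families_give_zero_and_one(self, septum_system, septum_modes):
        for md in septum_modes:
            frac = out_of_plane_fraction(md, septum_system.Mb, septum_system.Mm)
            if md.family == "membrane":
                assert frac == 0.0
            else:
                # consistent mass carries a small rotary-inertia share that
                # grows with modal curvature; far above the dash threshold
                assert frac > 0.9

    def test_synthetic_mixed_vector_gives_half(self, septum_system):
        """Equal transverse and rotary partitioned modal masses => fraction 0.5."""
        Mb = septum_system.Mb
        n = septum_system.n_nodes
        rng = np.random.default_rng(11)
        w_only = np.zeros(3 * n)
        w_only[0::3] = rng.standard_normal(n)
        th_only = np.zeros(3 * n)
        th_only[1::3] = rng.standard_normal(n)
        mw = w_only @ (Mb @ w_only)
        mt = th_only @ (Mb @ th_only)
        phi = w_only / np.sqrt(mw) + th_only / np.sqrt(mt)  # equal partitioned masses
        frac = out_of_plane_fraction(Mode(1.0, "bending", phi), Mb, septum_system.Mm)
        assert frac == pytest.approx(0.5, rel=1e-9)


class TestSignRegions:
    @pytest.fixture(scope="class")
    def plate(self):
        mesh, _ = rectangular_plate_fixture(0.03, 0.02, Material(), 2e-3,
                                            target_edge_length=1.5e-3)
        return mesh

    def test_single_lobe_counts_one(self, plate):
        w = np.ones(plate.n_nodes)
        count, orient = count_sign_regions(plate, w)
        assert count == 1
        assert orient == "none"

    def test_two_lobes_split_by_horizontal_nodal_line(self, plate):
        """sin(2 pi y / b): one sign flip along y, nodal line along x."""
        y = plate.nodes[:, 1]
        w = np.sin(2 * np.pi * y / 0.02)
        count, orient = count_sign_regions(plate, w)
        assert count == 2
        assert orient == "anteroposterior"

    def test_three_lobes_with_vertical_nodal_lines(self, plate):
        x = plate.nodes[:, 0]
        w = np.sin(3 * np.pi * x / 0.03)
        count, orient = count_sign_regions(plate, w)
        assert count == 3
        assert orient == "cephalocaudal"

    def test_matches_brute_force_flood_fill(self, plate):
        """Random smooth fields: count equals an independent BFS labeling."""
        rng = np.random.default_rng(5)
        x, y = plate.nodes[:, 0] / 0.03, plate.nodes[:, 1] / 0.02
        for _ in range(8):
            coef = rng.standard_normal((3, 3))
            w = sum(
                coef[i, j] * np.sin((i + 1) * np.pi * x) * np.sin((j + 1) * np.pi * y)
                for i in range(3) for j in range(3)
            )
            eps = 0.02
            count, _ = count_sign_regions(plate, w, eps=eps, min_peak_fraction=0.0)

            # independent BFS flood fill on the same sign graph
            wmax = np.abs(w).max()
            active = np.abs(w) >= eps * wmax
            adj = {i: set() for i in range(plate.n_nodes)}
            for a, b, c in plate.triangles:
                for u, v in ((a, b), (b, c), (c, a)):
                    adj[u].add(v)
                    adj[v].add(u)
            seen = set()
            brute = 0
            for start in range(plate.n_nodes):
                if not active[start] or start in seen:
                    continue
                brute += 1
                stack = [start]
                seen.add(start)
                while stack:
                    u = stack.pop()
                    for v in adj[u]:
                        if v not in seen and active[v] and np.sign(w[v]) == np.sign(w[u]):
                            seen.add(v)
                            stack.append(v)
            assert count == max(brute, 1)

    def test_all_zero_field_rejected(self, plate):
        with pytest.raises(ValueError):
            count_sign_regions(plate, np.zeros(plate.n_nodes))

    def test_eps_outside_range_rejected(self, plate):
        with pytest.raises(ValueError):
            count_sign_regions(plate, np.ones(plate.n_nodes), eps=0.5)


class TestClassifyMode:
    @pytest.fixture(scope="class")
    def regions(self, mesh):
        return landmark_regions(mesh, 3e-3)

    def test_membrane_mode_is_dash(self, septum_system, septum_modes, mesh, material, regions):
        membrane = [m for m in septum_modes if m.family == "membrane"][0]
        c = classify_mode(membrane, mesh, regions, material,
                          septum_system.Mb, septum_system.Mm)
        assert c.type_label == "-"
        assert c.type_numeric == 0
        assert c.sign_region_count is None

    def test_constructed_single_lobe_is_type_I(self, septum_system, mesh, material, regions):
        phi = np.zeros(3 * mesh.n_nodes)
        phi[0::3] = 1.0
        c = classify_mode(Mode(1.0, "bending", phi), mesh, regions, material,
                          septum_system.Mb, septum_system.Mm)
        assert c.type_label == "I"

    def test_constructed_three_lobe_is_type_III_anteroposterior(
        self, septum_system, mesh, material, regions
    ):
        """Two nodal lines running along x => S-shape, anteroposterior."""
        y = mesh.nodes[:, 1]
        ylo, yhi = y.min(), y.max()
        phi = np.zeros(3 * mesh.n_nodes)
        phi[0::3] = np.sin(3 * np.pi * (y - ylo) / (yhi - ylo))
        c = classify_mode(Mode(1.0, "bending", phi), mesh, regions, material,
                          septum_system.Mb, septum_system.Mm)
        assert c.type_label == "III"
        assert c.nodal_line_orientation == "anteroposterior"

    def test_sign_flip_and_scaling_invariance(self, septum_system, septum_modes,
                                              mesh, material, regions):
        Mb, Mm = septum_system.Mb, septum_system.Mm
        for md in list(septum_modes)[:4]:
            base = classify_mode(md, mesh, regions, material, Mb, Mm)
            for factor in (-1.0, 3.5, -0.2):
                scaled = Mode(md.frequency, md.family, factor * md.shape)
                c = classify_mode(scaled, mesh, regions, material, Mb, Mm)
                assert c.type_label == base.type_label
                assert c.sign_region_count == base.sign_region_count
                assert c.nodal_line_orientation == base.nodal_line_orientation
                assert [h[0] for h in c.hotspots] == [h[0] for h in base.hotspots]

    def test_hotspots_ranked_descending_nonnegative(self, septum_system, septum_modes,
                                                    mesh, material, regions):
        c = classify_mode(septum_modes[0], mesh, regions, material,
                          septum_system.Mb, septum_system.Mm)
        vals = [v for _, v in c.hotspots]
        assert all(v >= 0 for v in vals)
        assert vals == sorted(vals, reverse=True)
        assert set(h[0] for h in c.hotspots) == {"ANS", "BC_junction", "VEJ", "vomerine_groove"}

    def test_modal_von_mises_nonnegative_both_families(self, septum_modes, mesh, material):
        for md in list(septum_modes)[:3]:
            vm = modal_von_mises(md, mesh, material)
            assert vm.shape == (mesh.n_elements,)
            assert np.all(vm >= 0)


class TestClassifyModeset:
    def test_all_membrane_toy_set_is_all_dash(self, septum_system, mesh, material):
        regions = landmark_regions(mesh, 3e-3)
        membrane = solve_membrane_modes(septum_system, 3)
        cls = classify_modeset(membrane, mesh, regions, material,
                               septum_system.Mb, septum_system.Mm)
        assert [c.type_label for c in cls] == ["-", "-", "-"]

    def test_empty_modeset_rejected(self, septum_system, mesh, material):
        regions = landmark_regions(mesh, 3e-3)
        with pytest.raises(ValueError):
            classify_modeset(ModeSet([]), mesh, regions, material,
                             septum_system.Mb, septum_system.Mm)

    def test_type_summary_counts(self, spring_run):
        summary = type_summary(spring_run.classifications)
        assert sum(summary.values()) == 10
        assert summary["I"] >= 1 and summary["II"] >= 1 and summary["III"] >= 1

    def test_classification_deterministic_across_reruns(self):
        a = run_pipeline(RunConfig())
        b = run_pipeline(RunConfig())
        assert a.type_sequence == b.type_sequence
        assert np.array_equal(a.modes.frequencies, b.modes.frequencies)


class TestSpringEffect:
    def test_spring_reduces_static_tip_deflection(self, mesh, material):
        """Unit transverse tip load: the 20 kN/m spring strictly stiffens the tip."""
        import scipy.sparse.linalg as spla
        import scipy.sparse as sp

        tip = mesh.tip_node
        disps = {}
        for spring in (None, TipSpring(20e3)):
            sysm = assemble_system(mesh, material, spring)
            K, _ = sysm.reduced("bending")
            f = np.zeros(3 * sysm.n_nodes)
            f[3 * tip] = 1.0
            u = spla.spsolve(sp.csc_matrix(K), f[sysm.free_b])
            full = sysm.expand("bending", u)
            disps[spring is None] = abs(full[3 * tip])
        assert disps[False] < disps[True]
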