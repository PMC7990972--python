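import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import celldosim.geometry as G
from celldosim.geometry import (BOUNDARY_TOL, CYTOSOL, MEMBRANE, NUCLEUS,
                                OUTSIDE, CellGeometry, PlacementError,
                                PlacementSpec, build_cho_cell,
                                export_topas_parameters, geometry_to_frame,
                                gold_mass_percent, parse_topas_parameters,
                                place_nanoparticles, region_at,
                                sample_point_in_cytosol,
                                sample_point_in_sphere, sphere_overlap,
                                trace_path, validate_geometry)


def bare_cell(**kwargs):
    """Cell with no organelles beyond the nucleus unless overridden."""
    kwargs.setdefault("n_mitochondria", 0)
    kwargs.setdefault("rng", np.random.default_rng(0))
    return build_cho_cell(**kwargs)


class TestBuild:
    def test_default_build_has_90_valid_mitochondria(self, default_geom):
        assert default_geom.n_mitochondria == 90
        assert validate_geometry(default_geom) == []

    def test_zero_mitochondria(self):
        geom = bare_cell()
        assert geom.mitochondria == []
        assert validate_geometry(geom) == []

    def test_oversized_nucleus_rejected(self):
        with pytest.raises(ValueError, match="nucleus"):
            build_cho_cell(nucleus_radius=6001.0)

    def test_crowded_cytosol_raises_placement_error(self):
        # mitochondria physically cannot fit between nucleus and membrane
        with pytest.raises(PlacementError):
            build_cho_cell(nucleus_radius=5000.0, mitochondrion_radius=600.0,
                           n_mitochondria=5, rng=np.random.default_rng(0))

    def test_build_deterministic_given_seed(self):
        a = build_cho_cell(rng=np.random.default_rng(7))
        b = build_cho_cell(rng=np.random.default_rng(7))
        assert np.array_equal(a.mito_centers, b.mito_centers)


class TestSphereOverlap:
    def test_identical_spheres_overlap(self):
        assert sphere_overlap([0, 0, 0], 1.0, [0, 0, 0], 1.0)

    def test_tangent_spheres_do_not_overlap(self):
        assert not sphere_overlap([0, 0, 0], 1.0, [2.0, 0, 0], 1.0)

    def test_surface_attached_nanoparticle_is_legal(self):
        assert not sphere_overlap([0, 0, 0], 3300.0, [3305.0, 0, 0], 5.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0.1, 50), st.floats(0.1, 50), st.floats(0, 100))
    def test_symmetry_and_distance_criterion(self, r1, r2, d):
        c1, c2 = np.zeros(3), np.array([d, 0.0, 0.0])
        assert sphere_overlap(c1, r1, c2, r2) == sphere_overlap(c2, r2, c1, r1)
        assert sphere_overlap(c1, r1, c2, r2) == (d < r1 + r2 - BOUNDARY_TOL)


class TestSampling:
    def test_zero_radius_returns_center(self):
        p = sample_point_in_sphere([1, 2, 3], 0.0, np.random.default_rng(0))
        assert np.allclose(p, [1, 2, 3])

    def test_uniform_in_ball_moments(self):
        # for U uniform in the unit ball, r^3 ~ U(0,1) and the mean is the
        # centre by symmetry
        n = 100_000
        pts = sample_point_in_sphere(np.zeros(3), 1.0,
                                     np.random.default_rng(3), size=n)
        r3 = np.linalg.norm(pts, axis=1) ** 3
        se_r3 = np.sqrt(1.0 / 12.0 / n)
        assert abs(r3.mean() - 0.5) < 3 * se_r3
        se_axis = np.sqrt(0.2 / n)  # Var(x) = <r^2>/3 = (3/5)/3
        assert np.all(np.abs(pts.mean(axis=0)) < 3 * se_axis)

    def test_cytosol_sampling_avoids_organelles(self, default_geom):
        pts = sample_point_in_cytosol(default_geom,
                                      np.random.default_rng(4), size=10_000)
        r = np.linalg.norm(pts, axis=1)
        assert np.all(r <= default_geom.inner_radius)
        assert np.all(r >= default_geom.nucleus.radius)
        d2 = ((pts[:, None, :] - default_geom.mito_centers[None]) ** 2).sum(2)
        assert not (d2 < default_geom.mito_radii ** 2).any()

    def test_cytosol_radial_shell_fraction_matches_volume_ratio(self):
        geom = bare_cell()
        n = 10_000
        pts = sample_point_in_cytosol(geom, np.random.default_rng(5), size=n)
        r = np.linalg.norm(pts, axis=1)
        lo, hi = 3300.0, 4000.0
        expected = (hi ** 3 - lo ** 3) / (geom.inner_radius ** 3 - lo ** 3)
        frac = np.mean((r >= lo) & (r <= hi))
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 3 * se


class TestPlacement:
    def test_all_targeted_nanoparticles_touch_nucleus_surface(self):
        geom = bare_cell()
        place_nanoparticles(geom, PlacementSpec(10_000, 5.0, 1.0),
                            np.random.default_rng(6))
        d = np.linalg.norm(geom.np_centers, axis=1)
        assert np.all(np.abs(d - 3305.0) < 1e-6)
        assert validate_geometry(geom) == []

    def test_zero_count_leaves_geometry_unchanged(self, default_geom):
        n_before = default_geom.n_nanoparticles
        place_nanoparticles(default_geom, PlacementSpec(0, 5.0),
                            np.random.default_rng(0))
        assert default_geom.n_nanoparticles == n_before

    def test_targeted_mean_position_is_nucleus_center(self):
        geom = bare_cell()
        n = 1000
        place_nanoparticles(geom, PlacementSpec(n, 5.0, 1.0),
                            np.random.default_rng(8))
        se_axis = 3305.0 / np.sqrt(3 * n)
        assert np.all(np.abs(geom.np_centers.mean(axis=0)) < 3 * se_axis)

    def test_mitochondria_targeting_touches_host_surface(self, default_geom):
        geom = build_cho_cell(rng=np.random.default_rng(9))
        place_nanoparticles(
            geom, PlacementSpec(500, 5.0, 1.0, target=G.ROLE_MITOCHONDRION),
            np.random.default_rng(9))
        d = np.linalg.norm(geom.np_centers[:, None, :]
                           - geom.mito_centers[None], axis=2).min(axis=1)
        assert np.all(np.abs(d - 468.0) < 1e-6)
        assert validate_geometry(geom) == []

    def test_cytosol_placement_radially_uniform(self):
        # chi-square against analytic shell volumes, 10 shells, alpha=0.001
        geom = bare_cell()
        n = 10_000
        r_np = 5.0
        place_nanoparticles(geom, PlacementSpec(n, r_np, 0.0),
                            np.random.default_rng(10))
        r = np.linalg.norm(geom.np_centers, axis=1)
        edges = np.linspace(0.0, geom.inner_radius - r_np, 11)
        vol = np.clip(edges ** 3, 3300.0 ** 3, None)  # exclude the nucleus
        expected = np.diff(vol) / (vol[-1] - vol[0]) * n
        counts, _ = np.histogram(r, bins=edges)
        keep = expected > 0
        chi2 = ((counts[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        crit = stats.chi2.ppf(0.999, df=keep.sum() - 1)
        assert chi2 < crit

    def test_unplaceable_spec_reports_progress(self):
        geom = bare_cell()
        # far more surface nanoparticles than fit on the nucleus
        with pytest.raises(PlacementError, match="placed only"):
            place_nanoparticles(geom,
                                PlacementSpec(2000, 300.0, 1.0,
                                              max_attempts=20),
                                np.random.default_rng(11))

    @settings(derandomize=True, max_examples=10, deadline=None)
    @given(seed=st.integers(0, 2 ** 31), n_np=st.integers(0, 300),
           frac=st.floats(0.0, 1.0), r_np=st.floats(2.0, 30.0))
    def test_random_placements_always_validate(self, seed, n_np, frac, r_np):
        rng = np.random.default_rng(seed)
        geom = build_cho_cell(n_mitochondria=20, rng=rng)
        place_nanoparticles(geom, PlacementSpec(n_np, r_np, frac), rng)
        assert validate_geometry(geom) == []


class TestRegionAt:
    def test_named_points(self, default_geom):
        assert region_at(default_geom, [0, 0, 0]) == NUCLEUS
        assert region_at(default_geom, [0, 0, 5995.0]) == MEMBRANE
        assert region_at(default_geom, [0, 0, 7000.0]) == OUTSIDE

    def test_membrane_inner_surface_belongs_to_cytosol(self):
        geom = bare_cell()
        assert region_at(geom, [5990.0, 0, 0]) == CYTOSOL
        assert region_at(geom, [6000.0, 0, 0]) == MEMBRANE

    def test_agrees_with_brute_force_containment(self, small_geom):
        geom = small_geom
        n = 30_000
        rng = np.random.default_rng(12)
        pts = rng.uniform(-6100, 6100, size=(n, 3))
        centers = np.concatenate([
            geom.np_centers, geom.mito_centers,
            geom.nucleus.center[None, :]])
        radii = np.concatenate([
            geom.np_radii, geom.mito_radii, [geom.nucleus.radius]])
        ids = ([geom.region_id(G.ROLE_NANOPARTICLE, j)
                for j in range(geom.n_nanoparticles)]
               + [geom.region_id(G.ROLE_MITOCHONDRION, j)
                  for j in range(geom.n_mitochondria)]
               + [NUCLEUS])
        d = np.linalg.norm(pts[:, None, :] - centers[None], axis=2)
        inside = d <= radii[None, :] + BOUNDARY_TOL
        r = np.linalg.norm(pts, axis=1)
        expected = np.where(r > geom.cell_radius + BOUNDARY_TOL, OUTSIDE,
                            np.where(r > geom.inner_radius + BOUNDARY_TOL,
                                     MEMBRANE, CYTOSOL))
        first = inside.argmax(axis=1)
        hit = inside.any(axis=1)
        expected[hit] = np.array(ids)[first[hit]]
        got = np.array([region_at(geom, p) for p in pts])
        assert np.array_equal(got, expected)


class TestTracePath:
    def test_organelle_free_cell_from_center(self):
        geom = bare_cell(nucleus_radius=1.0)  # nucleus shrunk out of the way
        segs = trace_path(geom, [0, 0, 2.0], [0, 0, 1.0])
        roles = [s.region_id for s in segs]
        assert roles == [CYTOSOL, MEMBRANE]
        assert segs[0].length == pytest.approx(5988.0, abs=1e-9)
        assert segs[1].length == pytest.approx(10.0, abs=1e-9)

    def test_chords_through_nucleus(self):
        geom = bare_cell()
        segs = trace_path(geom, [5000.0, 0, 0], [-1.0, 0, 0])
        assert [s.region_id for s in segs] == [CYTOSOL, NUCLEUS, CYTOSOL,
                                               MEMBRANE]
        np.testing.assert_allclose([s.length for s in segs],
                                   [1700.0, 6600.0, 2690.0, 10.0], atol=1e-9)

    def test_origin_outside_yields_outside_segment(self, default_geom):
        segs = trace_path(default_geom, [0, 0, 9000.0], [0, 0, 1.0],
                          max_length=50.0)
        assert len(segs) == 1 and segs[0].region_id == OUTSIDE

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_segment_lengths_sum_to_exit_distance(self, small_geom, seed):
        rng = np.random.default_rng(seed)
        origin = G.sample_point_in_sphere(np.zeros(3), 5900.0, rng)
        direction = G.sample_unit_vectors(rng)
        segs = trace_path(small_geom, origin, direction)
        b = origin @ direction
        t_exit = -b + np.sqrt(b * b - (origin @ origin
                                       - small_geom.cell_radius ** 2))
        assert sum(s.length for s in segs) == pytest.approx(t_exit, abs=1e-6)


class TestGoldMassPercent:
    @pytest.mark.parametrize("n_np,r_np,expected", [
        (10_000, 3.0, 2.4e-3),
        (10_000, 5.0, 1.1e-2),
        (40_000, 5.0, 0.044),
    ])
    def test_printed_mass_percentages(self, default_geom, n_np, r_np, expected):
        value = gold_mass_percent(PlacementSpec(n_np, r_np), default_geom)
        assert value == pytest.approx(expected, rel=0.05)

    def test_zero_nanoparticles(self, default_geom):
        assert gold_mass_percent(PlacementSpec(0, 5.0), default_geom) == 0.0


class TestValidation:
    def test_coincident_nanoparticles_flagged(self, default_geom):
        geom = build_cho_cell(n_mitochondria=0, rng=np.random.default_rng(0))
        mat = geom.materials[G.ROLE_NANOPARTICLE]
        for i in range(2):
            geom.nanoparticles.append(G.SphereRegion(
                G.REGION_BASE + i, G.ROLE_NANOPARTICLE,
                np.array([4000.0, 0, 0]), 5.0, mat))
        geom.invalidate()
        violations = validate_geometry(geom)
        assert [v.kind for v in violations] == ["overlap"]

    def test_membrane_protrusion_flagged(self):
        geom = bare_cell()
        mat = geom.materials[G.ROLE_NANOPARTICLE]
        geom.nanoparticles.append(G.SphereRegion(
            G.REGION_BASE, G.ROLE_NANOPARTICLE,
            np.array([5999.0, 0, 0]), 5.0, mat))
        geom.invalidate()
        kinds = {v.kind for v in validate_geometry(geom)}
        assert kinds == {"containment"}


class TestExport:
    def test_topas_export_contains_nucleus_radius(self, default_geom):
        text = export_topas_parameters(default_geom)
        assert "NucleusRadius = 3300.0 nm" in text

    def test_no_nanoparticle_block_when_empty(self, default_geom):
        text = export_topas_parameters(default_geom, PlacementSpec(1, 5.0))
        assert "NumberOfNanoparticles" in text
        text = export_topas_parameters(default_geom)
        assert "Nanoparticle" not in text

    def test_radii_round_trip_exactly(self, default_geom):
        spec = PlacementSpec(123, 4.5, 0.5)
        parsed = parse_topas_parameters(
            export_topas_parameters(default_geom, spec))
        assert parsed["Ge/MyCell/CellRadius"] == default_geom.cell_radius
        assert parsed["Ge/MyCell/Nucleus/NucleusRadius"] == 3300.0
        assert parsed["Ge/MyCell/Nanoparticle/Radius"] == 4.5
        assert parsed["Ge/MyCell/Nanoparticle/NumberAtSurface"] == 62

    def test_csv_dump_has_one_row_per_sphere(self, small_geom):
        frame = geometry_to_frame(small_geom)
        assert len(frame) == 1 + 1 + 5 + 10  # world + nucleus + mito + NP
        assert set(frame.columns) == {"role", "id", "x", "y", "z", "radius",
                                      "material"}
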