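"""Element quality (Jacobian, aspect, quad angles) and clinical annotation
(spinopelvic parameters, GAP score, classification, inclusion filter)."""

import numpy as np
import pytest

from vertemorph.meshkit import ElementBlock, FEModel, MeshError, \
    make_spine_constellation
from vertemorph.metrics import (
    SpinoPelvicParams, aspect_ratio, classify_deformity, gap_score,
    inclusion_filter, jacobian_determinants, jacobian_ratio, max_quad_angle,
    measure_spinopelvic, validate_mesh,
)

UNIT_CUBE = np.array([[0., 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                      [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]])


def random_hex(rng, distortion=0.25) -> np.ndarray:
    return UNIT_CUBE + rng.uniform(-distortion, distortion, size=(8, 3))


def fd_jacobian_dets(coords, kind="hex8", h=1e-6):
    """Finite-difference oracle: numerically differentiate the
    isoparametric map at each Gauss point."""
    from vertemorph.metrics import _gauss_points, _hex8_dN, _hex20_dN

    def shape_N(xi, kind):
        # values via differentiating is circular; evaluate the map from
        # its defining interpolation instead
        if kind == "hex8":
            from vertemorph.metrics import _HEX8_XI as g
            x, y, z = xi
            return 0.125 * (1 + g[:, 0] * x) * (1 + g[:, 1] * y) * (1 + g[:, 2] * z)
        from vertemorph.metrics import _HEX8_XI as gc, _HEX20_MID as gm
        x, y, z = xi
        N = np.empty(20)
        for i, (a, b, c) in enumerate(gc):
            N[i] = 0.125 * (1 + a * x) * (1 + b * y) * (1 + c * z) \
                * (a * x + b * y + c * z - 2)
        for k, (a, b, c) in enumerate(gm):
            if a == 0:
                N[8 + k] = 0.25 * (1 - x * x) * (1 + b * y) * (1 + c * z)
            elif b == 0:
                N[8 + k] = 0.25 * (1 + a * x) * (1 - y * y) * (1 + c * z)
            else:
                N[8 + k] = 0.25 * (1 + a * x) * (1 + b * y) * (1 - z * z)
        return N

    dets = []
    for xi in _gauss_points(kind):
        J = np.empty((3, 3))
        for d in range(3):
            xp, xm = xi.copy(), xi.copy()
            xp[d] += h
            xm[d] -= h
            J[d] = (shape_N(xp, kind) - shape_N(xm, kind)) @ coords / (2 * h)
        dets.append(np.linalg.det(J))
    return np.asarray(dets)


class TestJacobian:
    def test_unit_cube_perfect(self):
        r, valid = jacobian_ratio(UNIT_CUBE)
        assert valid
        assert r == pytest.approx(1.0)

    def test_inverted_cube_invalid(self):
        bad = UNIT_CUBE.copy()
        bad[[0, 1]] = bad[[1, 0]]  # swap two bottom nodes
        _, valid = jacobian_ratio(bad)
        assert not valid

    def test_degenerate_flat_element_invalid(self):
        flat = UNIT_CUBE.copy()
        flat[:, 2] = 0.0  # all nodes coplanar: zero volume mapping
        _, valid = jacobian_ratio(flat)
        assert not valid

    def test_matches_finite_difference_oracle(self, rng):
        for _ in range(50):
            coords = random_hex(rng)
            ana = jacobian_determinants(coords, "hex8")
            num = fd_jacobian_dets(coords, "hex8")
            np.testing.assert_allclose(ana, num, rtol=1e-6, atol=1e-8)

    def test_hex20_matches_finite_difference(self, rng):
        base = random_hex(rng, 0.15)
        mids = []
        edges = [(0, 1), (1, 2), (2, 3), (3, 0), (4, 5), (5, 6), (6, 7),
                 (7, 4), (0, 4), (1, 5), (2, 6), (3, 7)]
        for a, b in edges:
            mids.append(0.5 * (base[a] + base[b]))
        coords = np.vstack([base, mids])
        ana = jacobian_determinants(coords, "hex20")
        num = fd_jacobian_dets(coords, "hex20")
        np.testing.assert_allclose(ana, num, rtol=1e-5, atol=1e-8)

    def test_validity_agreement_on_random_hexes(self, rng):
        """Determinant signs agree with the finite-difference oracle on
        1000 random hexes, with no disagreements."""
        disagreements = 0
        for _ in range(1000):
            coords = random_hex(rng, distortion=0.45)
            ana_valid = bool(np.all(jacobian_determinants(coords) > 0))
            num_valid = bool(np.all(fd_jacobian_dets(coords) > 1e-9))
            disagreements += ana_valid != num_valid
        assert disagreements == 0


class TestAspectAndAngles:
    def test_cube_aspect_one(self):
        assert aspect_ratio(UNIT_CUBE) == pytest.approx(1.0)

    def test_long_box_flagged_value(self):
        box = UNIT_CUBE * np.array([20.0, 1.0, 1.0])
        assert aspect_ratio(box) == pytest.approx(20.0)

    def test_random_box_vs_edge_scan(self, rng):
        coords = random_hex(rng)
        edges = [(0, 1), (1, 2), (2, 3), (3, 0), (4, 5), (5, 6), (6, 7),
                 (7, 4), (0, 4), (1, 5), (2, 6), (3, 7)]
        L = [np.linalg.norm(coords[a] - coords[b]) for a, b in edges]
        assert aspect_ratio(coords) == pytest.approx(max(L) / min(L))

    def test_zero_edge_infinite(self):
        bad = UNIT_CUBE.copy()
        bad[1] = bad[0]
        assert aspect_ratio(bad) == np.inf

    def test_square_angles(self):
        sq = np.array([[0., 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]])
        assert max_quad_angle(sq) == pytest.approx(90.0)

    def test_constructed_170_degree_corner(self):
        a = np.radians(10.0)  # interior angle at B = 180 - 10 = 170
        quad = np.array([[0.0, 0, 0], [1, 0, 0],
                         [1 + np.cos(a), np.sin(a), 0], [0.0, 1.5, 0]])
        assert max_quad_angle(quad) == pytest.approx(170.0, abs=1e-6)

    def test_random_quads_vs_vector_oracle(self, rng):
        done = 0
        while done < 20:
            # convex planar quads: sorted angular order around the centroid
            pts2 = rng.normal(size=(4, 2)) * 3
            c = pts2.mean(axis=0)
            ang = np.arctan2(*(pts2 - c).T[::-1])
            pts2 = pts2[np.argsort(ang)]
            def cross2(u, v):
                return u[0] * v[1] - u[1] * v[0]
            cross = [cross2(pts2[(i + 1) % 4] - pts2[i],
                            pts2[(i + 2) % 4] - pts2[(i + 1) % 4])
                     for i in range(4)]
            if not (all(v > 0 for v in cross) or all(v < 0 for v in cross)):
                continue  # oracle below assumes convexity
            done += 1
            quad = np.column_stack([pts2, np.zeros(4)])
            oracle = []
            for i in range(4):
                u = quad[(i - 1) % 4] - quad[i]
                v = quad[(i + 1) % 4] - quad[i]
                cosv = u @ v / np.linalg.norm(u) / np.linalg.norm(v)
                oracle.append(np.degrees(np.arccos(np.clip(cosv, -1, 1))))
            assert max_quad_angle(quad) == pytest.approx(max(oracle))

    def test_bowtie_flagged(self):
        bow = np.array([[0., 0, 0], [1, 1, 0], [1, 0, 0], [0, 1, 0]])
        assert max_quad_angle(bow) == 180.0


def hex_grid_model(nx=5, ny=5, nz=4, jitter=0.0, rng=None) -> FEModel:
    xs = np.arange(nx + 1.0)
    ys = np.arange(ny + 1.0)
    zs = np.arange(nz + 1.0)
    pts = np.array([[x, y, z] for z in zs for y in ys for x in xs])
    if jitter and rng is not None:
        pts = pts + rng.uniform(-jitter, jitter, pts.shape)

    def nid(i, j, k):
        return 1 + i + (nx + 1) * (j + (ny + 1) * k)

    conn = []
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                conn.append([nid(i, j, k), nid(i + 1, j, k),
                             nid(i + 1, j + 1, k), nid(i, j + 1, k),
                             nid(i, j, k + 1), nid(i + 1, j, k + 1),
                             nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1)])
    return FEModel(node_ids=np.arange(1, len(pts) + 1), node_coords=pts,
                   element_blocks=[ElementBlock(
                       name="GRID", kind="hex8",
                       element_ids=np.arange(1, len(conn) + 1),
                       connectivity=np.asarray(conn))])


class TestValidateMesh:
    def test_all_cube_mesh_clean(self):
        rep = validate_mesh(hex_grid_model())
        assert rep.percent_errors == 0.0
        assert rep.percent_warnings == 0.0

    def test_planted_inverted_elements_counted_exactly(self, rng):
        model = hex_grid_model(nx=5, ny=5, nz=4)  # 100 elements
        block = model.element_blocks[0]
        idx = model.node_index()
        planted = [3, 41, 77]
        for eid in planted:
            row = block.connectivity[eid - 1].copy()
            row[[0, 1]] = row[[1, 0]]  # invert
            block.connectivity[eid - 1] = row
        rep = validate_mesh(model)
        assert rep.percent_errors == pytest.approx(3.0)
        bad = rep.element_ids[~rep.valid]
        assert sorted(bad.tolist()) == planted

    def test_summary_recomputes_from_flags(self, rng):
        model = hex_grid_model(jitter=0.2, rng=rng)
        rep = validate_mesh(model)
        n_hex = sum(1 for k in rep.kinds if k in ("hex8", "hex20"))
        assert rep.percent_errors == pytest.approx(
            100.0 * np.sum(~rep.valid) / n_hex)


class TestSpinopelvic:
    def test_identity_pi_pt_ss(self):
        s, reg = make_spine_constellation(pt_deg=20.0, ss_deg=30.0)
        p = measure_spinopelvic(s, reg)
        assert p.pi == pytest.approx(p.pt + p.ss, abs=1e-9)
        assert p.pi == pytest.approx(50.0, abs=1e-9)

    def test_llpi_exemplar_arithmetic(self):
        # printed pair PI 78.39, LL -73.76 -> LL-PI mismatch 4.63
        s, reg = make_spine_constellation(pt_deg=24.71, ss_deg=53.68,
                                          ll_deg=-73.76)
        p = measure_spinopelvic(s, reg)
        assert p.pi == pytest.approx(78.39, abs=1e-9)
        assert p.llpi == pytest.approx(4.63, abs=1e-9)

    def test_sagittal_params_invariant_to_vertical_rotation(self):
        # the sagittal frame follows the hip axis, so rotating the patient
        # about the vertical must leave every sagittal parameter unchanged
        s, reg = make_spine_constellation(pt_deg=22.0, ss_deg=33.0,
                                          ll_deg=-50.0, cobb_deg=12.0)
        p0 = measure_spinopelvic(s, reg)
        a = np.radians(40.0)
        Rz = np.array([[np.cos(a), -np.sin(a), 0],
                       [np.sin(a), np.cos(a), 0], [0, 0, 1.0]])
        from vertemorph.meshkit import Shape
        rotated = Shape(s.points @ Rz.T + np.array([7.0, -4.0, 2.0]))
        p1 = measure_spinopelvic(rotated, reg)
        for attr in ("pi", "pt", "ss", "ll", "ldi", "gt", "tpa", "sva",
                     "cobb"):
            assert getattr(p1, attr) == pytest.approx(getattr(p0, attr),
                                                      abs=1e-6), attr

    def test_pi_invariant_under_arbitrary_rigid_transform(self, rng):
        from vertemorph.meshkit import Shape
        s, reg = make_spine_constellation(pt_deg=18.0, ss_deg=36.0)
        p0 = measure_spinopelvic(s, reg)
        # rotate within the sagittal plane (the anatomical frame is a
        # convention; in-plane rotation must not change PI)
        a = np.radians(17.0)
        Rx = np.array([[1.0, 0, 0], [0, np.cos(a), -np.sin(a)],
                       [0, np.sin(a), np.cos(a)]])
        moved = Shape(s.points @ Rx.T + np.array([5.0, -3.0, 11.0]))
        p1 = measure_spinopelvic(moved, reg)
        assert p1.pi == pytest.approx(p0.pi, abs=1e-6)

    def test_missing_landmark_named(self):
        s, reg = make_spine_constellation()
        del reg.landmarks["c7_center"]
        with pytest.raises(MeshError, match="c7_center"):
            measure_spinopelvic(s, reg)


def params_with(**kw) -> SpinoPelvicParams:
    base = dict(pi=50.0, pt=20.0, ss=30.0, ll=-50.0, llpi=0.0, gt=20.0,
                rpv=0.0, rll=0.0, ldi=60.0, rsa=0.0, tpa=15.0, sva=10.0,
                cobb=5.0)
    base.update(kw)
    return SpinoPelvicParams(**base)


class TestGap:
    def test_exemplar_components_score_one(self):
        p = params_with(rpv=-1.57, rll=-3.84, ldi=55.37, rsa=9.20)
        assert gap_score(p, "adult") == 1

    def test_all_aligned_scores_zero(self):
        assert gap_score(params_with(), "adult") == 0

    def test_all_worst_scores_thirteen(self):
        p = params_with(rpv=-20.0, rll=-30.0, ldi=95.0, rsa=25.0)
        assert gap_score(p, "young") == 13

    def test_age_in_years_accepted(self):
        p = params_with(rsa=9.20)
        assert gap_score(p, 55) == 2
        assert gap_score(p, 70) == 1

    def test_missing_component_rejected(self):
        p = params_with(ldi=float("nan"))
        with pytest.raises(MeshError, match="ldi"):
            gap_score(p, "adult")


class TestClassification:
    @pytest.mark.parametrize("gap,expected", [
        (0, "aligned"), (1, "aligned"), (2, "aligned"),
        (3, "moderate"), (6, "moderate"),
        (7, "severe"), (13, "severe"),
    ])
    def test_sagittal_bins_full_sweep(self, gap, expected):
        p = params_with()
        p.gap = gap
        assert classify_deformity(p)[0] == expected

    @pytest.mark.parametrize("cobb,expected", [
        (9.9, "none"), (10.0, "moderate"), (15.0, "moderate"),
        (20.0, "moderate"), (20.1, "severe"),
    ])
    def test_scoliosis_bins(self, cobb, expected):
        p = params_with(cobb=cobb)
        p.gap = 1
        assert classify_deformity(p)[1] == expected


class TestInclusion:
    def test_typical_deformity_included(self):
        p = params_with(llpi=12.0, pt=25.0, sva=60.0)
        assert inclusion_filter(60, p)

    def test_age_excludes(self):
        p = params_with(llpi=12.0, pt=25.0, sva=60.0)
        assert not inclusion_filter(40, p)

    @pytest.mark.parametrize("field,value", [
        ("llpi", 10.0), ("pt", 20.0), ("sva", 50.0),
    ])
    def test_boundaries_are_strict(self, field, value):
        kw = dict(llpi=12.0, pt=25.0, sva=60.0)
        kw[field] = value
        assert not inclusion_filter(60, params_with(**kw))
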