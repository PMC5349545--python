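"""Reference trajectory, anisotropic projection, rank-order MC, ellipse test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import biasdx as bx
from biasdx.model_free import (
    Ellipse,
    ellipses_intersect,
    panel_intrinsic_activities,
)


def _logistic2_fit(ln_c, b, ligand="REF", assay="a", var=1e-6):
    return bx.Logistic2Fit(ligand, assay, ln_c, b, np.eye(2) * var, 0.0, 8)


def _traj(c=1e-8, cp=1e-8, b=1.0, bp=1.0):
    return bx.ReferenceTrajectory(_logistic2_fit(np.log(c), b),
                                  _logistic2_fit(np.log(cp), bp, assay="b"))


def _ia(lig, assay, ia, sd=0.02):
    return bx.IntrinsicActivity(lig, assay, ia, sd)


def _shared_ias(panel_a, panel_b):
    ia_a = panel_intrinsic_activities(panel_a)
    ia_b = panel_intrinsic_activities(panel_b)
    shared = [l for l in ia_a if l in ia_b and l != panel_a.reference_ligand]
    return [ia_a[l] for l in shared], [ia_b[l] for l in shared]


class TestReferenceTrajectory:
    def test_identity_when_fits_equal(self):
        traj = _traj()
        y = np.linspace(0.01, 0.99, 50)
        np.testing.assert_allclose(traj.curve(y), y, atol=1e-12)

    def test_closed_form_tenfold_potency_shift(self):
        # b = b' = 1, c' = 10c: Y'(0.5) = 1/11
        traj = _traj(c=1e-8, cp=1e-7)
        assert traj.curve(0.5) == pytest.approx(1.0 / 11.0, abs=1e-12)

    def test_closed_form_matches_parametric_sweep(self):
        traj = _traj(c=2e-8, cp=9e-8, b=1.4, bp=0.8)
        conc = np.geomspace(1e-12, 1e-2, 1000)
        y_a = traj.fit_a.predict(conc)
        y_b = traj.fit_b.predict(conc)
        assert np.max(np.abs(traj.curve(y_a) - y_b)) < 1e-10

    @settings(max_examples=50, deadline=None)
    @given(
        b=st.floats(0.3, 4.0), bp=st.floats(0.3, 4.0),
        lc=st.floats(-25.0, -5.0), lcp=st.floats(-25.0, -5.0),
    )
    def test_monotone_with_unit_interval_endpoints(self, b, bp, lc, lcp):
        traj = bx.ReferenceTrajectory(_logistic2_fit(lc, b),
                                      _logistic2_fit(lcp, bp, assay="b"))
        y = np.linspace(1e-6, 1.0 - 1e-6, 200)
        out = traj.curve(y)
        # strictly increasing up to float saturation at the extremes
        assert np.all(np.diff(out) >= 0)
        interior = (out > 1e-12) & (out < 1.0 - 1e-12)
        assert np.all(np.diff(out[interior]) > 0)
        # endpoint interpolation: (0,0) and (1,1) in the limit — for shallow
        # slope ratios the approach is a slow power law, so probe deep
        with np.errstate(under="ignore"):
            tiny = float(np.exp(-500.0 * b / bp))
        probe = max(tiny, 1e-280)
        assert traj.curve(probe) < 1e-3
        assert traj.curve(1.0 - probe) > 1.0 - 1e-3

    def test_inverse_round_trip(self):
        traj = _traj(c=2e-8, cp=9e-8, b=1.4, bp=0.8)
        y = np.linspace(0.05, 0.95, 19)
        np.testing.assert_allclose(traj.inverse(traj.curve(y)), y, atol=1e-10)

    def test_build_trajectory_requires_same_ligand(self, noiseless_panels):
        panel_a, panel_b, _ = noiseless_panels
        with pytest.raises(ValueError, match="same"):
            bx.build_trajectory(panel_a.curves["REF"], panel_b.curves["L03"])


class TestProjection:
    def test_point_on_trajectory_projects_to_itself(self):
        traj = _traj(c=1e-8, cp=5e-8, b=1.2, bp=0.9)
        y0 = 0.37
        p = bx.project_point(_ia("l", "a", y0), _ia("l", "b", float(traj.curve(y0))),
                             traj)
        assert p.distance == pytest.approx(0.0, abs=1e-6)
        assert p.projected[0] == pytest.approx(y0, abs=1e-6)

    def test_identity_trajectory_symmetric_point(self):
        # equal sds, observed (0.6, 0.4): nearest identity point is (0.5, 0.5)
        p = bx.project_point(_ia("l", "a", 0.6, 0.05), _ia("l", "b", 0.4, 0.05),
                             _traj())
        assert p.projected[0] == pytest.approx(0.5, abs=1e-6)
        assert p.projected[1] == pytest.approx(0.5, abs=1e-6)
        assert p.distance ** 2 == pytest.approx(2 * (0.1 / 0.05) ** 2, rel=1e-6)

    def test_optimizer_beats_dense_grid(self):
        rng = np.random.default_rng(3)
        traj = _traj(c=1e-8, cp=7e-8, b=1.5, bp=0.7)
        grid = np.linspace(1e-9, 1 - 1e-9, 100_000)
        gx = traj.curve(grid)
        for _ in range(20):
            oa, ob = rng.uniform(0.05, 1.05), rng.uniform(0.05, 1.05)
            sa, sb = rng.uniform(0.01, 0.1, 2)
            p = bx.project_point(_ia("l", "a", oa, sa), _ia("l", "b", ob, sb), traj)
            brute = np.min(((grid - oa) / sa) ** 2 + ((gx - ob) / sb) ** 2)
            assert p.distance ** 2 <= brute + 1e-8

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError, match="ia_sd"):
            bx.project_point(_ia("l", "a", 0.5, 0.0), _ia("l", "b", 0.5, 0.1), _traj())


class TestMethod8:
    def test_vanishing_sds_put_ranks_on_diagonal_with_no_flags(self, noiseless_panels):
        panel_a, panel_b, _ = noiseless_panels
        traj = bx.build_trajectory(panel_a.reference_curve, panel_b.reference_curve)
        ias_a, ias_b = _shared_ias(panel_a, panel_b)
        tiny_a = [bx.IntrinsicActivity(i.ligand_id, i.assay_id, i.ia, 1e-9) for i in ias_a]
        tiny_b = [bx.IntrinsicActivity(i.ligand_id, i.assay_id, i.ia, 1e-9) for i in ias_b]
        res = bx.method8_rank_order(tiny_a, tiny_b, traj, n_mc=2000, seed=0)
        assert res.flagged == ()
        for ra, rb in res.observed_ranks.values():
            assert ra == rb

    def test_injected_bias_is_flagged(self):
        cfg = bx.SimConfig(seed=9, noise_sd=0.02, bias_map={"L06": 0.05})
        panel_a, panel_b, _ = bx.simulate_panels(cfg)
        traj = bx.build_trajectory(panel_a.reference_curve, panel_b.reference_curve)
        ias_a, ias_b = _shared_ias(panel_a, panel_b)
        res = bx.method8_rank_order(ias_a, ias_b, traj, n_mc=20_000, seed=1)
        assert "L06" in res.flagged

    def test_deterministic_given_seed(self, noisy_panels):
        panel_a, panel_b, _ = noisy_panels
        traj = bx.build_trajectory(panel_a.reference_curve, panel_b.reference_curve)
        ias_a, ias_b = _shared_ias(panel_a, panel_b)
        r1 = bx.method8_rank_order(ias_a, ias_b, traj, n_mc=5000, seed=11)
        r2 = bx.method8_rank_order(ias_a, ias_b, traj, n_mc=5000, seed=11)
        assert np.array_equal(r1.joint_density, r2.joint_density)
        assert r1.flagged == r2.flagged

    def test_density_normalized_per_ligand(self, noisy_panels):
        panel_a, panel_b, _ = noisy_panels
        traj = bx.build_trajectory(panel_a.reference_curve, panel_b.reference_curve)
        ias_a, ias_b = _shared_ias(panel_a, panel_b)
        res = bx.method8_rank_order(ias_a, ias_b, traj, n_mc=2000, seed=0)
        np.testing.assert_allclose(res.joint_density.sum(axis=(1, 2)), 1.0)

    def test_refuses_tiny_mc(self, noisy_panels):
        panel_a, panel_b, _ = noisy_panels
        traj = bx.build_trajectory(panel_a.reference_curve, panel_b.reference_curve)
        ias_a, ias_b = _shared_ias(panel_a, panel_b)
        with pytest.raises(ValueError, match="n_mc"):
            bx.method8_rank_order(ias_a, ias_b, traj, n_mc=500)


class TestEllipses:
    def test_circle_separation_geometry(self):
        a = Ellipse(0.0, 0.0, 1.0, 1.0)
        assert not ellipses_intersect(a, Ellipse(3.0, 0.0, 1.0, 1.0))
        assert ellipses_intersect(a, Ellipse(1.5, 0.0, 1.0, 1.0))

    def test_contained_ellipse_intersects(self):
        outer = Ellipse(0.0, 0.0, 2.0, 1.0)
        inner = Ellipse(0.1, 0.0, 0.2, 0.1)
        assert ellipses_intersect(outer, inner)
        assert ellipses_intersect(inner, outer)

    def test_verdicts_match_boundary_sampling_brute_force(self):
        rng = np.random.default_rng(12)
        t = np.linspace(0, 2 * np.pi, 3600)
        disagreements = 0
        for _ in range(300):
            e1 = Ellipse(*rng.uniform(-1, 1, 2), *rng.uniform(0.05, 1.0, 2),
                         rng.uniform(0, np.pi))
            e2 = Ellipse(*rng.uniform(-1, 1, 2), *rng.uniform(0.05, 1.0, 2),
                         rng.uniform(0, np.pi))
            bx1, by1 = e1.boundary(t)
            bx2, by2 = e2.boundary(t)
            brute = (
                bool(np.any(e1.contains(bx2, by2)))
                or bool(np.any(e2.contains(bx1, by1)))
                or bool(e1.contains(np.array(e2.cx), np.array(e2.cy)))
            )
            if ellipses_intersect(e1, e2) != brute:
                disagreements += 1
        assert disagreements == 0


class TestMethod9:
    def test_point_on_trajectory_not_flagged(self, noiseless_panels):
        panel_a, panel_b, _ = noiseless_panels
        traj = bx.build_trajectory(panel_a.reference_curve, panel_b.reference_curve)
        y0 = 0.45
        res = bx.method9_distance(
            [_ia("l", panel_a.assay_id, y0)],
            [_ia("l", panel_b.assay_id, float(traj.curve(y0)))], traj)
        assert len(res) == 1 and res[0].intersects and not res[0].flagged

    def test_single_test_ligand_far_off_trajectory_flagged(self, noisy_panels):
        panel_a, panel_b, _ = noisy_panels
        traj = bx.build_trajectory(panel_a.reference_curve, panel_b.reference_curve)
        res = bx.method9_distance([_ia("l", "a", 0.95, 0.01)],
                                  [_ia("l", "b", 0.05, 0.01)], traj)
        assert res[0].flagged

    def test_flags_invariant_under_assay_swap(self):
        cfg = bx.SimConfig(seed=9, noise_sd=0.02, bias_map={"L06": 0.05})
        panel_a, panel_b, _ = bx.simulate_panels(cfg)
        traj = bx.build_trajectory(panel_a.reference_curve, panel_b.reference_curve)
        ias_a, ias_b = _shared_ias(panel_a, panel_b)
        fwd = {r.ligand_id: r.flagged for r in bx.method9_distance(ias_a, ias_b, traj)}
        rev = {r.ligand_id: r.flagged
               for r in bx.method9_distance(ias_b, ias_a, traj.swapped())}
        assert fwd == rev and fwd["L06"]

    def test_detects_five_sigma_displacement(self, noiseless_panels):
        panel_a, panel_b, _ = noiseless_panels
        traj = bx.build_trajectory(panel_a.reference_curve, panel_b.reference_curve)
        sd = 0.02
        y0 = 0.5
        on = float(traj.curve(y0))
        res = bx.method9_distance([_ia("l", "a", y0, sd)],
                                  [_ia("l", "b", on + 8 * sd, sd)], traj)
        assert res[0].flagged
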