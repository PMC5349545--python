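"""Methods 1-7: null faithfulness, bias recovery, equivalences, MC band."""

import numpy as np
import pytest

import biasdx as bx
from biasdx.model_based import (
    EquieffectivePair,
    equieffective_occupancy_ratio,
    equieffective_pairs,
)
from conftest import make_operational_curve


def _bias_map(results):
    return {r.ligand_id: r.bias_factor for r in results}


def _all_methods(panel_a, panel_b, kds):
    return {m: bx.compute_bias(panel_a, panel_b, m, kds) for m in range(1, 8)}


class TestNullFaithfulness:
    def test_pure_system_bias_gives_zero_for_all_methods(self, noiseless_panels,
                                                         noiseless_kds):
        # different transfer functions, shared efficacies: no ligand bias exists
        panel_a, panel_b, _ = noiseless_panels
        for method, results in _all_methods(panel_a, panel_b, noiseless_kds).items():
            worst = max(abs(r.bias_factor) for r in results if r.bias_factor is not None)
            assert worst < 1e-3, f"method {method} reports bias {worst} with none present"

    def test_identical_panels_give_exact_zero(self, noiseless_panels, noiseless_kds):
        panel_a, _, _ = noiseless_panels
        twin = bx.AssayPanel(panel_a.assay_id, dict(panel_a.curves),
                             panel_a.reference_ligand)
        for method in (3, 7):
            for r in bx.compute_bias(panel_a, twin, method, noiseless_kds):
                assert r.bias_factor == 0.0

    def test_reference_ligand_is_exactly_zero(self, noiseless_panels, noiseless_kds):
        panel_a, panel_b, _ = noiseless_panels
        for results in _all_methods(panel_a, panel_b, noiseless_kds).values():
            assert _bias_map(results)["REF"] == 0.0


class TestBiasRecovery:
    def test_tenfold_injection_recovers_one_log_unit(self, injected_panels,
                                                     injected_cfg):
        panel_a, panel_b, truth = injected_panels
        kds = injected_cfg.kds()
        expected = truth.set_index("ligand")["expected_bias_factor"]
        assert expected["L06"] == 1.0
        for method, results in _all_methods(panel_a, panel_b, kds).items():
            bm = _bias_map(results)
            assert bm["L06"] == pytest.approx(1.0, abs=1e-3), f"method {method}"
            others = [abs(v) for k, v in bm.items() if k != "L06" and v is not None]
            assert max(others) < 1e-3, f"method {method} leaks bias onto unbiased ligands"

    def test_antisymmetry_under_panel_swap(self, injected_panels, injected_cfg):
        panel_a, panel_b, _ = injected_panels
        kds = injected_cfg.kds()
        for method in range(1, 8):
            fwd = _bias_map(bx.compute_bias(panel_a, panel_b, method, kds))
            rev = _bias_map(bx.compute_bias(panel_b, panel_a, method, kds))
            for lig, b in fwd.items():
                if b is None:
                    continue
                assert rev[lig] == pytest.approx(-b, abs=1e-9)


class TestEquieffectiveOccupancy:
    def test_identical_fits_give_unit_ratio_and_half_occupancy_at_kd(self):
        fit = bx.fit_logistic3(make_operational_curve(tau=5.0, kd=1e-6))
        kd = bx.LigandKd("LIG", -6.0)
        ratio = equieffective_occupancy_ratio(fit, fit, kd, kd, [0.2, 0.4, 0.6])
        assert ratio == pytest.approx(1.0, rel=1e-12)
        pair = equieffective_pairs(fit, fit, kd, kd, [0.5 * fit.e_max])[0]
        # occupancy at [L] = K_d is 1/2 by the binding isotherm
        at_kd = kd.kd / (kd.kd + kd.kd)
        assert at_kd == 0.5
        assert isinstance(pair, EquieffectivePair) and 0.0 < pair.occ_ref < 1.0

    def test_relative_efficacy_recovered_from_curves(self):
        # equal K_d and K_E, eps_test/eps_ref = 0.2 at unit slope
        ref = bx.fit_logistic3(make_operational_curve("REF", tau=10.0, kd=1e-6))
        test = bx.fit_logistic3(make_operational_curve("T", tau=2.0, kd=1e-6))
        kd = bx.LigandKd("x", -6.0)
        levels = np.linspace(0.1, 0.9, 9) * min(ref.e_max, test.e_max)
        ratio = equieffective_occupancy_ratio(ref, test, kd, kd, levels)
        assert ratio == pytest.approx(0.2, abs=1e-3)

    def test_infeasible_levels_rejected(self):
        ref = bx.fit_logistic3(make_operational_curve("REF", tau=10.0))
        weak = bx.fit_logistic3(make_operational_curve("W", tau=0.2))
        kd = bx.LigandKd("x", -6.0)
        with pytest.raises(ValueError, match="no feasible response level"):
            equieffective_pairs(ref, weak, kd, kd, [0.9 * ref.e_max])


class TestClosedFormEquivalences:
    def test_method3_equals_method2_at_unit_slope(self, noiseless_panels):
        # E_max/EC50 = r_max tau/K_d exactly when n = 1
        panel_a, panel_b, _ = noiseless_panels
        m2 = _bias_map(bx.bias_method2(panel_a, panel_b))
        m3 = _bias_map(bx.bias_method3(panel_a, panel_b))
        for lig in m2:
            assert m3[lig] == pytest.approx(m2[lig], abs=1e-3)

    def test_level_strategies_agree_on_noiseless_data(self, noiseless_panels,
                                                      noiseless_kds):
        panel_a, panel_b, _ = noiseless_panels
        maps = [
            _bias_map(bx.bias_methods456(panel_a, panel_b, noiseless_kds, s))
            for s in ("single_level", "common_range", "optimized_range")
        ]
        for lig in maps[0]:
            vals = [m[lig] for m in maps if lig in m]
            assert max(vals) - min(vals) < 1e-6

    def test_method7_slope_equals_relative_eps_over_kd(self):
        # (eps/K_d)_test = 3 (eps/K_d)_ref in both panels -> slope 3, bias 0
        curves = {}
        for assay, ke in (("a", 0.3), ("b", 1.2)):
            curves[assay] = {
                "REF": make_operational_curve("REF", assay, tau=1.0 / ke, kd=1e-6),
                "T": make_operational_curve("T", assay, tau=3.0 / ke, kd=1e-6),
            }
        panel_a = bx.AssayPanel("a", curves["a"], "REF")
        panel_b = bx.AssayPanel("b", curves["b"], "REF")
        res = _bias_map(bx.bias_method7(panel_a, panel_b))
        assert res["T"] == pytest.approx(0.0, abs=1e-3)
        # independent slope check through the public logistic inverse
        fr = bx.fit_logistic3(curves["a"]["REF"])
        ft = bx.fit_logistic3(curves["a"]["T"])
        levels = np.linspace(0.1, 0.9, 10) * min(fr.e_max, ft.e_max)
        inv_r = np.array([1.0 / bx.inverse_response(fr, lv) for lv in levels])
        inv_t = np.array([1.0 / bx.inverse_response(ft, lv) for lv in levels])
        slope = np.polyfit(inv_r, inv_t, 1)[0]
        assert slope == pytest.approx(3.0, abs=1e-3)


class TestMonteCarloNullBand:
    def test_zero_noise_band_collapses(self, noiseless_panels, noiseless_kds):
        panel_a, panel_b, _ = noiseless_panels
        lo, hi = bx.monte_carlo_null_band(panel_a, panel_b, 3, n_sim=100, seed=0,
                                          kds=noiseless_kds)
        assert hi - lo < 1e-9

    def test_band_roughly_symmetric_and_deterministic(self, noisy_panels):
        panel_a, panel_b, _ = noisy_panels
        band1 = bx.monte_carlo_null_band(panel_a, panel_b, 3, n_sim=150, seed=5)
        band2 = bx.monte_carlo_null_band(panel_a, panel_b, 3, n_sim=150, seed=5)
        assert band1 == band2
        lo, hi = band1
        assert lo < 0 < hi
        assert abs(lo + hi) < 0.5 * (hi - lo)

    def test_refuses_tiny_simulation(self, noisy_panels):
        panel_a, panel_b, _ = noisy_panels
        with pytest.raises(ValueError, match="n_sim"):
            bx.monte_carlo_null_band(panel_a, panel_b, 3, n_sim=50)

    def test_flags_follow_band_membership(self, noisy_panels):
        panel_a, panel_b, _ = noisy_panels
        results = bx.bias_method3(panel_a, panel_b)
        flagged = bx.apply_null_band(results, (-0.01, 0.01))
        for r in flagged:
            expect = r.bias_factor is not None and not (-0.01 <= r.bias_factor <= 0.01)
            assert r.flagged == expect


class TestSummaries:
    def test_rms_and_hit_rate_arithmetic(self):
        pairs = [("a", "b"), ("a", "c")]
        results = []
        for i in range(10):
            for j, pair in enumerate(pairs):
                results.append(bx.BiasResult(f"L{i}", 4, pair,
                                             1.0 if i % 2 else -1.0,
                                             flagged=(i, j) in {(0, 0), (1, 0), (2, 1)}))
        s = bx.summarize_methods(results)
        assert s.rms_deviation == pytest.approx(1.0)
        assert s.hit_rate == pytest.approx(3 / (10 * 2))

    def test_all_zero_bias(self):
        results = [bx.BiasResult(f"L{i}", 4, ("a", "b"), 0.0) for i in range(5)]
        s = bx.summarize_methods(results)
        assert s.rms_deviation == 0.0 and s.hit_rate == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bx.summarize_methods([])
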