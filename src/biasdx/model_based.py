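"""Bias factors from classical receptor theory: methods 1-7.

All seven methods express, per ligand, a log10 ratio across two assays of a
relative-efficacy quantity scaled to a shared reference agonist:

1. operational-model tau ratios, K_d fixed from binding data
2. operational-model tau/K_d ratios, K_d free
3. E_max/EC50 ratios from 3-parameter logistic fits (equals method 2 when the
   slope factor is ~1)
4. equi-effective occupancy ratios at a single response level
5. the same over multiple levels in a range common to all agonists
6. the same over per-pair optimized level ranges
7. slopes of the double-reciprocal regression of equi-effective concentrations
   (Furchgott plot; slope estimates relative epsilon/K_d)

Significance is assessed against a Monte Carlo null band obtained by a
parametric bootstrap under the no-bias null hypothesis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .curve_fitting import (
    FitError,
    Logistic3Fit,
    fit_logistic3,
    fit_operational_panel,
    inverse_response,
)
from .data_model import AssayPanel, BiasResult, LigandKd

__all__ = [
    "EquieffectivePair",
    "MethodSummary",
    "bias_method1",
    "bias_method2",
    "bias_method3",
    "bias_methods456",
    "bias_method7",
    "compute_bias",
    "equieffective_pairs",
    "equieffective_occupancy_ratio",
    "monte_carlo_null_band",
    "apply_null_band",
    "summarize_methods",
]

_LOG10 = np.log(10.0)

#: level-selection defaults (fractions of the relevant fitted E_max)
SINGLE_LEVEL_FRACTION = 0.5
COMMON_RANGE = (0.2, 0.8)
OPTIMIZED_RANGE = (0.1, 0.9)
N_LEVELS = 10
SLOPE_WARN_THRESHOLD = 0.3  # |n - 1| beyond which method 3 attaches a warning

_STRATEGY_IDS = {"single_level": 4, "common_range": 5, "optimized_range": 6}


@dataclass(frozen=True)
class EquieffectivePair:
    """Equi-effective concentrations of reference and test ligand at one level."""

    level: float
    conc_ref: float
    conc_test: float
    occ_ref: Optional[float] = None
    occ_test: Optional[float] = None


@dataclass(frozen=True)
class MethodSummary:
    """Global performance indicators of one method over a result set."""

    method_id: int
    rms_deviation: float
    hit_rate: float
    n_ligands: int
    n_comparisons: int
    known_unbiased: bool = False


# ---------------------------------------------------------------------------
# shared plumbing
# ---------------------------------------------------------------------------

def _shared_ligands(panel_a: AssayPanel, panel_b: AssayPanel) -> List[str]:
    if panel_a.reference_ligand != panel_b.reference_ligand:
        raise ValueError(
            f"panels must share the reference ligand "
            f"({panel_a.reference_ligand!r} != {panel_b.reference_ligand!r})"
        )
    return [l for l in panel_a.ligands if l in panel_b.curves]


def _result(lig: str, method_id: int, pair: Tuple[str, str], bias: Optional[float],
            warns: Sequence[str] = ()) -> BiasResult:
    return BiasResult(lig, method_id, pair, bias, warnings=tuple(warns))


def _log10_cross_ratio(rel_a: float, rel_b: float) -> float:
    return float((np.log(rel_a) - np.log(rel_b)) / _LOG10)


# ---------------------------------------------------------------------------
# operational-model strategies (methods 1-3)
# ---------------------------------------------------------------------------

def bias_method1(panel_a: AssayPanel, panel_b: AssayPanel,
                 kds: Dict[str, LigandKd], weighted: bool = False) -> List[BiasResult]:
    """Method 1: log10 ratio of tau ratios, operational fits with K_d fixed.

    The tau values come from a global operational fit of each panel with the
    system parameters (r_max, slope) shared across ligands and each ligand's
    K_d fixed from binding data — sharing the system maximum is what pins tau
    for partial agonists, whose own curve does not constrain r_max.
    """
    ligands = _shared_ligands(panel_a, panel_b)
    pair = (panel_a.assay_id, panel_b.assay_id)
    ref = panel_a.reference_ligand
    missing = [l for l in ligands if l not in kds]
    for lig in missing:
        warnings.warn(f"method 1: no K_d for {lig!r}; ligand skipped", stacklevel=2)
    usable = [l for l in ligands if l in kds]
    ln_tau: Dict[Tuple[str, str], float] = {}
    results: List[BiasResult] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for panel in (panel_a, panel_b):
            try:
                fits = fit_operational_panel(
                    {l: panel.curves[l] for l in usable},
                    {l: kds[l] for l in usable}, weighted=weighted,
                )
            except FitError as exc:
                raise ValueError(f"method 1: global fit of {panel.assay_id!r} "
                                 f"failed: {exc}") from exc
            for lig, fit in fits.items():
                ln_tau[(panel.assay_id, lig)] = fit.ln_tau
    if ref not in usable:
        raise ValueError("method 1: reference ligand could not be fitted (or lacks K_d)")
    for lig in usable:
        if lig == ref:
            results.append(_result(lig, 1, pair, 0.0))
            continue
        b = (
            (ln_tau[(pair[0], lig)] - ln_tau[(pair[0], ref)])
            - (ln_tau[(pair[1], lig)] - ln_tau[(pair[1], ref)])
        ) / _LOG10
        results.append(_result(lig, 1, pair, float(b)))
    return results


def bias_method2(panel_a: AssayPanel, panel_b: AssayPanel,
                 weighted: bool = False) -> List[BiasResult]:
    """Method 2: log10 ratio of tau/K_d ratios, operational fits with K_d free.

    The tau/K_d composites come from a global operational fit of each panel
    with the system parameters (r_max, slope) shared across ligands — sharing
    the system maximum is what identifies the composite for partial agonists.
    """
    ligands = _shared_ligands(panel_a, panel_b)
    pair = (panel_a.assay_id, panel_b.assay_id)
    ref = panel_a.reference_ligand
    ltk: Dict[Tuple[str, str], float] = {}
    usable = list(ligands)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for panel in (panel_a, panel_b):
            try:
                fits = fit_operational_panel(
                    {l: panel.curves[l] for l in ligands}, weighted=weighted
                )
            except FitError as exc:
                raise ValueError(f"method 2: global fit of {panel.assay_id!r} "
                                 f"failed: {exc}") from exc
            for lig, fit in fits.items():
                ltk[(panel.assay_id, lig)] = fit.ln_tau_over_kd
    if ref not in usable:
        raise ValueError("method 2: reference ligand could not be fitted")
    results = []
    for lig in usable:
        if lig == ref:
            results.append(_result(lig, 2, pair, 0.0))
            continue
        b = (
            (ltk[(pair[0], lig)] - ltk[(pair[0], ref)])
            - (ltk[(pair[1], lig)] - ltk[(pair[1], ref)])
        ) / _LOG10
        results.append(_result(lig, 2, pair, float(b)))
    return results


def _logistic3_fits(panel: AssayPanel, weighted: bool) -> Dict[str, Logistic3Fit]:
    fits = {}
    for lig, curve in panel.curves.items():
        try:
            fits[lig] = fit_logistic3(curve, weighted=weighted)
        except FitError as exc:
            warnings.warn(f"{exc}; ligand {lig!r} skipped", stacklevel=2)
    return fits


def bias_method3(panel_a: AssayPanel, panel_b: AssayPanel, weighted: bool = False,
                 slope_warn: float = SLOPE_WARN_THRESHOLD) -> List[BiasResult]:
    """Method 3: log10 ratio of reference-scaled E_max/EC50 ratios.

    Equivalent to method 2 only near slope 1; ligands whose fitted slope
    deviates from 1 by more than *slope_warn* carry a warning.
    """
    ligands = _shared_ligands(panel_a, panel_b)
    pair = (panel_a.assay_id, panel_b.assay_id)
    ref = panel_a.reference_ligand
    fits = {panel_a.assay_id: _logistic3_fits(panel_a, weighted),
            panel_b.assay_id: _logistic3_fits(panel_b, weighted)}
    if ref not in fits[pair[0]] or ref not in fits[pair[1]]:
        raise ValueError("method 3: reference ligand could not be fitted")

    def ln_q(assay: str, lig: str) -> float:
        f = fits[assay][lig]
        return float(np.log(f.e_max) - f.ln_ec50)

    results = []
    for lig in ligands:
        if lig not in fits[pair[0]] or lig not in fits[pair[1]]:
            continue
        warns = []
        for assay in pair:
            n = fits[assay][lig].slope_n
            if abs(n - 1.0) > slope_warn:
                warns.append(
                    f"slope {n:.2f} in {assay} deviates from 1; the E_max/EC50 ~ "
                    "tau/K_d equivalence is unreliable"
                )
        if lig == ref:
            results.append(_result(lig, 3, pair, 0.0, warns))
            continue
        b = (
            (ln_q(pair[0], lig) - ln_q(pair[0], ref))
            - (ln_q(pair[1], lig) - ln_q(pair[1], ref))
        ) / _LOG10
        results.append(_result(lig, 3, pair, float(b), warns))
    return results


# ---------------------------------------------------------------------------
# null-method strategies (methods 4-7)
# ---------------------------------------------------------------------------

def equieffective_pairs(fit_ref: Logistic3Fit, fit_test: Logistic3Fit,
                        kd_ref: Optional[LigandKd], kd_test: Optional[LigandKd],
                        levels: Sequence[float]) -> List[EquieffectivePair]:
    """Equi-effective concentrations (and occupancies when K_d is known)."""
    feasible = [lv for lv in levels if 0.0 < lv < min(fit_ref.e_max, fit_test.e_max)]
    if not feasible:
        raise ValueError(
            f"no feasible response level for pair ({fit_ref.ligand_id!r}, "
            f"{fit_test.ligand_id!r}): requested levels all exceed an E_max"
        )
    out = []
    for lv in feasible:
        cr = inverse_response(fit_ref, lv)
        ct = inverse_response(fit_test, lv)
        occ_r = cr / (cr + kd_ref.kd) if kd_ref is not None else None
        occ_t = ct / (ct + kd_test.kd) if kd_test is not None else None
        out.append(EquieffectivePair(lv, cr, ct, occ_r, occ_t))
    return out


def equieffective_occupancy_ratio(fit_ref: Logistic3Fit, fit_test: Logistic3Fit,
                                  kd_ref: LigandKd, kd_test: LigandKd,
                                  levels: Sequence[float]) -> float:
    """Relative efficacy eps_test/eps_ref = O_ref/O_test at equi-effective
    concentrations, combined across levels on the log scale (geometric mean)."""
    pairs = equieffective_pairs(fit_ref, fit_test, kd_ref, kd_test, levels)
    logs = [np.log(p.occ_ref / p.occ_test) for p in pairs]
    return float(np.exp(np.mean(logs)))


def _levels_for(strategy: str, fits: Dict[str, Logistic3Fit], ligands: Sequence[str],
                ref: str, lig: str, single_level_fraction: float,
                common_range: Tuple[float, float],
                optimized_range: Tuple[float, float], n_levels: int) -> np.ndarray:
    if strategy == "single_level":
        base = min(fits[l].e_max for l in ligands)
        return np.array([single_level_fraction * base])
    if strategy == "common_range":
        base = min(fits[l].e_max for l in ligands)
        return np.linspace(common_range[0], common_range[1], n_levels) * base
    if strategy == "optimized_range":
        base = min(fits[ref].e_max, fits[lig].e_max)
        return np.linspace(optimized_range[0], optimized_range[1], n_levels) * base
    raise ValueError(f"unknown level strategy {strategy!r}")


def bias_methods456(panel_a: AssayPanel, panel_b: AssayPanel,
                    kds: Dict[str, LigandKd], strategy: str = "single_level",
                    weighted: bool = False,
                    single_level_fraction: float = SINGLE_LEVEL_FRACTION,
                    common_range: Tuple[float, float] = COMMON_RANGE,
                    optimized_range: Tuple[float, float] = OPTIMIZED_RANGE,
                    n_levels: int = N_LEVELS) -> List[BiasResult]:
    """Methods 4-6: log10 ratio across panels of equi-effective occupancy ratios.

    *strategy* selects the response levels: ``single_level`` (method 4; 50% of
    the smallest fitted E_max in the panel), ``common_range`` (method 5;
    10 levels over 20-80% of the common feasible range) or ``optimized_range``
    (method 6; 10 levels over 10-90% of each reference/test pair's own overlap
    of dynamic ranges).
    """
    method_id = _STRATEGY_IDS[strategy]
    ligands = _shared_ligands(panel_a, panel_b)
    pair = (panel_a.assay_id, panel_b.assay_id)
    ref = panel_a.reference_ligand
    missing = [l for l in ligands if l not in kds]
    for lig in missing:
        warnings.warn(f"method {method_id}: no K_d for {lig!r}; ligand skipped",
                      stacklevel=2)
    ligands = [l for l in ligands if l in kds]
    fits = {panel_a.assay_id: _logistic3_fits(panel_a, weighted),
            panel_b.assay_id: _logistic3_fits(panel_b, weighted)}
    ligands = [l for l in ligands if l in fits[pair[0]] and l in fits[pair[1]]]
    if ref not in ligands:
        raise ValueError(f"method {method_id}: reference ligand unusable")

    results = []
    for lig in ligands:
        if lig == ref:
            results.append(_result(lig, method_id, pair, 0.0))
            continue
        rel = {}
        warns: List[str] = []
        ok = True
        for assay in pair:
            f = fits[assay]
            levels = _levels_for(strategy, f, ligands, ref, lig,
                                 single_level_fraction, common_range,
                                 optimized_range, n_levels)
            feasible = levels[levels < f[lig].e_max]
            if feasible.size == 0:
                warns.append(
                    f"E_max of {lig!r} in {assay} lies below the common response "
                    "level; ligand excluded"
                )
                ok = False
                break
            if feasible.size < levels.size:
                warns.append(
                    f"{levels.size - feasible.size} level(s) above E_max of "
                    f"{lig!r} in {assay} dropped"
                )
            rel[assay] = equieffective_occupancy_ratio(
                f[ref], f[lig], kds[ref], kds[lig], feasible
            )
        if not ok:
            warnings.warn(f"method {method_id}: {warns[-1]}", stacklevel=2)
            continue
        results.append(_result(lig, method_id, pair,
                               _log10_cross_ratio(rel[pair[0]], rel[pair[1]]), warns))
    return results


def bias_method7(panel_a: AssayPanel, panel_b: AssayPanel, n_levels: int = N_LEVELS,
                 weighted: bool = False) -> List[BiasResult]:
    """Method 7: log10 ratio of double-reciprocal slopes.

    At equi-effective concentrations, 1/[L_test] = slope * 1/[L_ref] + intercept
    with slope = (eps_test/K_test)/(eps_ref/K_ref). Per panel that slope is
    estimated by least squares with free intercept over >=5 equi-effective
    levels spanning the shared response range; the bias factor is the log10
    ratio of the two panels' slopes.
    """
    if n_levels < 5:
        raise ValueError("method 7 needs >=5 equi-effective levels")
    ligands = _shared_ligands(panel_a, panel_b)
    pair = (panel_a.assay_id, panel_b.assay_id)
    ref = panel_a.reference_ligand
    fits = {panel_a.assay_id: _logistic3_fits(panel_a, weighted),
            panel_b.assay_id: _logistic3_fits(panel_b, weighted)}
    if ref not in fits[pair[0]] or ref not in fits[pair[1]]:
        raise ValueError("method 7: reference ligand could not be fitted")
    results = []
    for lig in ligands:
        if lig not in fits[pair[0]] or lig not in fits[pair[1]]:
            continue
        if lig == ref:
            results.append(_result(lig, 7, pair, 0.0))
            continue
        slopes = {}
        warns: List[str] = []
        valid = True
        for assay in pair:
            f = fits[assay]
            top = min(f[ref].e_max, f[lig].e_max)
            levels = np.linspace(OPTIMIZED_RANGE[0], OPTIMIZED_RANGE[1], n_levels) * top
            pairs = equieffective_pairs(f[ref], f[lig], None, None, levels)
            inv_ref = np.array([1.0 / p.conc_ref for p in pairs])
            inv_test = np.array([1.0 / p.conc_test for p in pairs])
            slope = float(np.polyfit(inv_ref, inv_test, 1)[0])
            if slope <= 0:
                warns.append(f"non-positive double-reciprocal slope in {assay}")
                valid = False
            slopes[assay] = slope
        if not valid:
            results.append(_result(lig, 7, pair, None, warns))
            continue
        results.append(_result(lig, 7, pair,
                               _log10_cross_ratio(slopes[pair[0]], slopes[pair[1]]),
                               warns))
    return results


# ---------------------------------------------------------------------------
# dispatch, Monte Carlo null band, summaries
# ---------------------------------------------------------------------------

def compute_bias(panel_a: AssayPanel, panel_b: AssayPanel, method_id: int,
                 kds: Optional[Dict[str, LigandKd]] = None,
                 weighted: bool = False) -> List[BiasResult]:
    """Run one of methods 1-7 by number."""
    if method_id in (1, 4, 5, 6) and not kds:
        raise ValueError(f"method {method_id} requires a K_d table")
    if method_id == 1:
        return bias_method1(panel_a, panel_b, kds, weighted)
    if method_id == 2:
        return bias_method2(panel_a, panel_b, weighted)
    if method_id == 3:
        return bias_method3(panel_a, panel_b, weighted)
    if method_id in (4, 5, 6):
        strategy = {4: "single_level", 5: "common_range", 6: "optimized_range"}[method_id]
        return bias_methods456(panel_a, panel_b, kds, strategy, weighted)
    if method_id == 7:
        return bias_method7(panel_a, panel_b, weighted=weighted)
    raise ValueError("method_id must be in 1..7 (methods 8-9 live in model_free)")


def _null_means(panel: AssayPanel) -> Dict[str, np.ndarray]:
    """Fitted logistic3 values per curve — the no-bias null means for resampling."""
    means = {}
    for lig, curve in panel.curves.items():
        try:
            means[lig] = fit_logistic3(curve).predict(curve.conc)
        except FitError:
            means[lig] = curve.resp.copy()
    return means


def monte_carlo_null_band(panel_a: AssayPanel, panel_b: AssayPanel, method_id: int,
                          n_sim: int = 500, seed: int = 0,
                          kds: Optional[Dict[str, LigandKd]] = None,
                          per_ligand: bool = False):
    """95% null band for bias factors by parametric bootstrap.

    Under the no-bias null, each curve's responses are resampled from
    Normal(fitted value, resp_sd) and all bias factors recomputed. Each
    resampled factor is centred at the ligand's point estimate (the basic
    bootstrap pivot b* - b_hat), so the pooled draws describe the estimator's
    dispersion about zero bias rather than about the input panels' own noise
    offsets; the 2.5th/97.5th percentiles of that pooled null distribution are
    returned as ``(ci_low, ci_high)`` (or a per-ligand dict when
    *per_ligand*). Deterministic given *seed*.
    """
    if n_sim < 100:
        raise ValueError("n_sim < 100 gives a meaningless 95% band; refused")
    rng = np.random.default_rng(seed)
    ref = panel_a.reference_ligand
    means = {panel_a.assay_id: _null_means(panel_a), panel_b.assay_id: _null_means(panel_b)}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        point = {
            r.ligand_id: r.bias_factor
            for r in compute_bias(panel_a, panel_b, method_id, kds)
            if r.bias_factor is not None
        }
    draws: Dict[str, List[float]] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_sim):
            resampled = []
            for panel in (panel_a, panel_b):
                curves = {}
                for lig, curve in panel.curves.items():
                    mu = means[panel.assay_id][lig]
                    resp = mu + rng.standard_normal(mu.size) * curve.resp_sd
                    curves[lig] = replace(curve, resp=resp)
                resampled.append(AssayPanel(panel.assay_id, curves, ref))
            try:
                results = compute_bias(resampled[0], resampled[1], method_id, kds)
            except (FitError, ValueError):
                continue
            for r in results:
                if r.ligand_id == ref or r.bias_factor is None:
                    continue
                if r.ligand_id not in point:
                    continue
                draws.setdefault(r.ligand_id, []).append(
                    r.bias_factor - point[r.ligand_id]
                )
    if not draws:
        raise RuntimeError("null-band bootstrap produced no usable bias factors")
    if per_ligand:
        return {
            lig: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
            for lig, v in draws.items()
        }
    pooled = np.concatenate([np.asarray(v) for v in draws.values()])
    return float(np.percentile(pooled, 2.5)), float(np.percentile(pooled, 97.5))


def apply_null_band(results: List[BiasResult], band: Tuple[float, float]) -> List[BiasResult]:
    """Attach a common null band and set the biased/unbiased flags."""
    lo, hi = band
    out = []
    for r in results:
        flagged = r.bias_factor is not None and not (lo <= r.bias_factor <= hi)
        out.append(replace(r, ci_low=lo, ci_high=hi, flagged=flagged))
    return out


def summarize_methods(results: List[BiasResult], known_unbiased: bool = False,
                      reference_ligand: Optional[str] = None) -> MethodSummary:
    """RMS deviation from zero bias and average positive-hit rate.

    The hit rate is the total number of flagged ligands divided by the number
    of ligands and the number of assay-pair comparisons. The reference ligand
    (zero by construction) is excluded when named.
    """
    rows = [r for r in results if r.ligand_id != reference_ligand]
    if not rows:
        raise ValueError("no results to summarize")
    method_ids = {r.method_id for r in rows}
    if len(method_ids) != 1:
        raise ValueError("summarize_methods expects results from a single method")
    factors = np.array([r.bias_factor for r in rows if r.bias_factor is not None])
    rms = float(np.sqrt(np.mean(factors ** 2))) if factors.size else float("nan")
    ligands = {r.ligand_id for r in rows}
    comparisons = {r.assay_pair for r in rows}
    hits = sum(r.flagged for r in rows)
    hit_rate = hits / (len(ligands) * len(comparisons))
    return MethodSummary(method_ids.pop(), rms, float(hit_rate),
                         len(ligands), len(comparisons), known_unbiased)
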