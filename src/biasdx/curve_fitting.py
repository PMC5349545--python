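"""Nonlinear regression of agonist concentration-response curves.

Three models are supported, all fitted in their log-concentration forms, which
are numerically better behaved than the plain-concentration parameterizations:

* 3-parameter logistic  r([L]) = E_max / (1 + (EC50/[L])^n)
* 2-parameter logistic  Y([L]) = 1 / (1 + (c/[L])^b)  (maximum pinned to 1)
* operational (Black-Leff) model
      E([L]) = r_max (tau [L])^n / (([L] + K_d)^n + (tau [L])^n)

The operational transduction coefficient tau = R_t/K_E carries the efficacy
information; R_t and K_E are not separately identifiable and exist only inside
tau. With K_d free, tau and K_d themselves are poorly identified for strong
agonists and only the composite tau/K_d is reliable; the fit still converges
and reports the composite.

Parameter covariance, standard errors and 95% confidence bands use the
standard asymptotic linearization of the least-squares estimator
(Gauss-Newton Jacobian at the optimum, t-quantile at the residual df).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .data_model import CRCurve, LigandKd

__all__ = [
    "FitError",
    "Logistic3Fit",
    "Logistic2Fit",
    "OperationalFit",
    "fit_logistic3",
    "fit_logistic2",
    "fit_operational",
    "fit_operational_panel",
    "inverse_response",
]

#: convergence tolerance on the least-squares objective
_FTOL = 1e-10
#: slope-factor bounds keeping the ill-identified regime finite
_SLOPE_BOUNDS = (0.2, 5.0)
_LNTAU_BOUNDS = (-12.0, 12.0)


class FitError(RuntimeError):
    """Nonlinear regression failed to converge (after multi-start)."""


# ---------------------------------------------------------------------------
# model functions on x = ln[L]
# ---------------------------------------------------------------------------

def _logistic3(x: np.ndarray, e_max: float, n: float, ln_ec50: float) -> np.ndarray:
    return e_max / (1.0 + np.exp(np.clip(n * (ln_ec50 - x), -500, 500)))


def _logistic2(x: np.ndarray, ln_c: float, b: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(np.clip(b * (ln_c - x), -500, 500)))


def _operational(x: np.ndarray, r_max: float, n: float, ln_tau: float,
                 ln_kd: float) -> np.ndarray:
    # E = r_max / (1 + exp(n*ln([L]+K_d) - n*(ln_tau + x))), stable via logaddexp
    z = n * np.logaddexp(x, ln_kd) - n * (ln_tau + x)
    return r_max / (1.0 + np.exp(np.clip(z, -500, 500)))


def _logistic3_jac(x: np.ndarray, e_max: float, n: float, ln_ec50: float) -> np.ndarray:
    u = np.clip(n * (ln_ec50 - x), -500, 500)
    sig = 1.0 / (1.0 + np.exp(u))
    d = -e_max * sig * (1.0 - sig)
    return np.column_stack([sig, d * (ln_ec50 - x), d * n])


def _logistic2_jac(x: np.ndarray, ln_c: float, b: float) -> np.ndarray:
    u = np.clip(b * (ln_c - x), -500, 500)
    sig = 1.0 / (1.0 + np.exp(u))
    d = -sig * (1.0 - sig)
    return np.column_stack([d * b, d * (ln_c - x)])


def _operational_jac(x: np.ndarray, r_max: float, n: float, ln_tau: float,
                     ln_kd: float, kd_free: bool) -> np.ndarray:
    a = np.logaddexp(x, ln_kd)
    z = np.clip(n * a - n * (ln_tau + x), -500, 500)
    sig = 1.0 / (1.0 + np.exp(z))
    dz = -r_max * sig * (1.0 - sig)
    cols = [sig, dz * (a - ln_tau - x), dz * (-n)]
    if kd_free:
        cols.append(dz * n / (1.0 + np.exp(np.clip(x - ln_kd, -500, 500))))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# shared least-squares machinery
# ---------------------------------------------------------------------------

def _multistart_ls(
    residual: Callable[[np.ndarray], np.ndarray],
    starts: Sequence[np.ndarray],
    bounds: Tuple[np.ndarray, np.ndarray],
    early_cost: Optional[float] = None,
    jac: "Callable[[np.ndarray], np.ndarray] | str" = "2-point",
) -> optimize.OptimizeResult:
    """Best-of-several least squares. Starts are ordered best-heuristic first;
    a start whose converged objective already reaches *early_cost* (a benchmark
    for the attainable minimum) is accepted without running the rest."""
    best = None
    errors = []
    for p0 in starts:
        p0 = np.clip(np.asarray(p0, float), bounds[0] + 1e-12, bounds[1] - 1e-12)
        try:
            res = optimize.least_squares(
                residual, p0, bounds=bounds, method="trf", jac=jac,
                ftol=_FTOL, xtol=1e-12, gtol=1e-12, max_nfev=5000,
            )
        except Exception as exc:  # noqa: BLE001 - collected for diagnostics
            errors.append(str(exc))
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
            if early_cost is not None and best.cost <= early_cost:
                break
    if best is None:
        raise FitError(f"no start converged; optimizer reports: {errors!r}")
    return best


def _asymptotic_cov(res: optimize.OptimizeResult, n_obs: int) -> Tuple[np.ndarray, float, int]:
    rss = float(2.0 * res.cost)
    dof = max(n_obs - res.x.size, 1)
    jtj = res.jac.T @ res.jac
    try:
        cov = np.linalg.inv(jtj) * (rss / dof)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(jtj) * (rss / dof)
    return cov, rss, dof


def _sigma_weights(curve: CRCurve, weighted: bool) -> Optional[np.ndarray]:
    if not weighted:
        return None
    sd = np.where(curve.resp_sd > 0, curve.resp_sd, np.nan)
    if np.all(np.isnan(sd)):
        return None
    fill = np.nanmedian(sd)
    return np.where(np.isnan(sd), fill, sd)


# ---------------------------------------------------------------------------
# fit result containers
# ---------------------------------------------------------------------------

@dataclass
class Logistic3Fit:
    """3-parameter logistic fit: E_max, slope n and ln EC50 with covariance."""

    ligand_id: str
    assay_id: str
    e_max: float
    slope_n: float
    ln_ec50: float
    cov: np.ndarray
    rss: float
    dof: int
    warnings: Tuple[str, ...] = field(default_factory=tuple)

    @property
    def ec50(self) -> float:
        return float(np.exp(self.ln_ec50))

    @property
    def e_max_se(self) -> float:
        return float(np.sqrt(max(self.cov[0, 0], 0.0)))

    def predict(self, conc: np.ndarray | float) -> np.ndarray:
        return _logistic3(np.log(np.asarray(conc, float)), self.e_max, self.slope_n, self.ln_ec50)

    def to_dict(self) -> dict:
        return {
            "model": "logistic3", "ligand": self.ligand_id, "assay": self.assay_id,
            "e_max": self.e_max, "slope_n": self.slope_n, "ln_ec50": self.ln_ec50,
            "cov": self.cov.tolist(), "rss": self.rss, "dof": self.dof,
            "warnings": list(self.warnings),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


@dataclass
class Logistic2Fit:
    """2-parameter logistic (maximum pinned at 1) with an asymptotic 95% band.

    Parameters are the midpoint c (``ec50_c``) and slope b (``slope_b``);
    covariance is on (ln c, b). Applies to reference-normalized curves only.
    """

    ligand_id: str
    assay_id: str
    ln_c: float
    slope_b: float
    cov: np.ndarray
    rss: float
    dof: int
    warnings: Tuple[str, ...] = field(default_factory=tuple)

    @property
    def ec50_c(self) -> float:
        return float(np.exp(self.ln_c))

    def predict(self, conc: np.ndarray | float) -> np.ndarray:
        return _logistic2(np.log(np.asarray(conc, float)), self.ln_c, self.slope_b)

    def predict_se(self, conc: np.ndarray | float) -> np.ndarray:
        """Delta-method standard error of the fitted curve at *conc*."""
        x = np.log(np.asarray(conc, float))
        y = _logistic2(x, self.ln_c, self.slope_b)
        dy = y * (1.0 - y)
        g_lnc = -self.slope_b * dy
        g_b = -(self.ln_c - x) * dy
        var = (
            g_lnc ** 2 * self.cov[0, 0]
            + 2.0 * g_lnc * g_b * self.cov[0, 1]
            + g_b ** 2 * self.cov[1, 1]
        )
        return np.sqrt(np.maximum(var, 0.0))

    def band(self, conc: np.ndarray | float, level: float = 0.95):
        """Pointwise asymptotic confidence band (lo, hi) of the fitted curve."""
        t = stats.t.ppf(0.5 + level / 2.0, self.dof)
        y = self.predict(conc)
        half = t * self.predict_se(conc)
        return y - half, y + half

    def to_dict(self) -> dict:
        return {
            "model": "logistic2", "ligand": self.ligand_id, "assay": self.assay_id,
            "ec50_c": self.ec50_c, "slope_b": self.slope_b,
            "cov": self.cov.tolist(), "rss": self.rss, "dof": self.dof,
            "warnings": list(self.warnings),
        }


@dataclass
class OperationalFit:
    """Operational-model fit: r_max, slope n, ln tau (and ln K_d when free)."""

    ligand_id: str
    assay_id: str
    r_max: float
    slope_n: float
    ln_tau: float
    ln_kd: float
    cov: np.ndarray
    rss: float
    dof: int
    kd_fixed: bool
    warnings: Tuple[str, ...] = field(default_factory=tuple)

    @property
    def tau(self) -> float:
        return float(np.exp(self.ln_tau))

    @property
    def kd(self) -> float:
        return float(np.exp(self.ln_kd))

    @property
    def ln_tau_over_kd(self) -> float:
        """Composite ln(tau/K_d) — the quantity that stays identified when K_d is free."""
        return self.ln_tau - self.ln_kd

    @property
    def e_max(self) -> float:
        tn = self.tau ** self.slope_n
        return self.r_max * tn / (1.0 + tn)

    @property
    def ec50(self) -> float:
        tn = self.tau ** self.slope_n
        return self.kd / ((2.0 + tn) ** (1.0 / self.slope_n) - 1.0)

    def predict(self, conc: np.ndarray | float) -> np.ndarray:
        return _operational(np.log(np.asarray(conc, float)), self.r_max, self.slope_n,
                            self.ln_tau, self.ln_kd)

    def to_dict(self) -> dict:
        return {
            "model": "operational", "ligand": self.ligand_id, "assay": self.assay_id,
            "r_max": self.r_max, "slope_n": self.slope_n, "ln_tau": self.ln_tau,
            "ln_kd": self.ln_kd, "kd_fixed": self.kd_fixed,
            "cov": self.cov.tolist(), "rss": self.rss, "dof": self.dof,
            "warnings": list(self.warnings),
        }


# ---------------------------------------------------------------------------
# fitting entry points
# ---------------------------------------------------------------------------

def _early_cost(curve: CRCurve, sigma: Optional[np.ndarray]) -> float:
    """Objective benchmark for early multi-start exit: a converged fit whose
    residual RMS is within 1.5x the curve's stated noise (or 3% of its span
    when no uncertainty is recorded) has plainly found the basin."""
    n = curve.resp.size
    if sigma is not None:
        return 0.5 * n * 1.5 ** 2
    med_sd = float(np.median(curve.resp_sd))
    span = max(float(curve.resp.max() - curve.resp.min()), 1e-9)
    rms = max(1.5 * med_sd, 0.03 * span)
    return 0.5 * n * rms ** 2


def _check_agonist_mode(curve: CRCurve) -> None:
    x = np.log(curve.conc)
    r = np.corrcoef(x, curve.resp)[0, 1]
    span = curve.resp.max() - curve.resp.min()
    if span > 0 and r < -0.3:
        raise FitError(
            f"{curve.ligand_id}/{curve.assay_id}: responses decrease with "
            "concentration; antagonist-mode curves are not supported"
        )


def _heuristic_logistic3_start(curve: CRCurve) -> Tuple[float, float, float]:
    x, y = np.log(curve.conc), curve.resp
    e0 = max(y.max(), 1e-9) * 1.02
    half = e0 / 2.0
    above = y >= half
    if above.any() and not above.all():
        i = int(np.argmax(above))
        m0 = x[i] if i == 0 else 0.5 * (x[i - 1] + x[i])
    else:
        m0 = float(np.median(x))
    return e0, 1.0, m0


def _fit_cache(curve: CRCurve) -> dict:
    # CRCurve is frozen (immutable content), so memoizing fits on the instance
    # is safe; repeated method calls on the same panel then share regressions
    cache = curve.__dict__.get("_fits")
    if cache is None:
        object.__setattr__(curve, "_fits", {})
        cache = curve.__dict__["_fits"]
    return cache


def fit_logistic3(curve: CRCurve, weighted: bool = False) -> Logistic3Fit:
    """Fit the 3-parameter logistic in its ln-concentration form.

    Least squares on the curve means (inverse-variance weighting optional);
    multi-start from plateau / half-max-crossing heuristics.
    """
    cache = _fit_cache(curve)
    key = ("l3", weighted)
    if key in cache:
        return cache[key]
    _check_agonist_mode(curve)
    x, y = np.log(curve.conc), curve.resp
    sigma = _sigma_weights(curve, weighted)

    def residual(p):
        r = _logistic3(x, *p) - y
        return r / sigma if sigma is not None else r

    def jac(p):
        j = _logistic3_jac(x, *p)
        return j / sigma[:, None] if sigma is not None else j

    e0, n0, m0 = _heuristic_logistic3_start(curve)
    starts = [
        (e0, n0, m0),
        (e0, 0.7, m0), (e0, 2.0, m0),
        (e0 * 1.5, n0, m0 + 2.0), (e0, n0, m0 - 2.0),
    ]
    lo = np.array([1e-12, _SLOPE_BOUNDS[0], x.min() - 30.0])
    hi = np.array([max(y.max(), 1e-9) * 20.0, _SLOPE_BOUNDS[1], x.max() + 30.0])
    early = _early_cost(curve, sigma)
    try:
        res = _multistart_ls(residual, starts, (lo, hi), early_cost=early, jac=jac)
    except FitError as exc:
        raise FitError(f"{curve.ligand_id}/{curve.assay_id}: logistic3 fit failed: {exc}") from exc
    cov, rss, dof = _asymptotic_cov(res, y.size)
    e_max, slope_n, ln_ec50 = res.x
    warns = []
    if not (x.min() - np.log(10.0) <= ln_ec50 <= x.max() + np.log(10.0)):
        warns.append(
            f"fitted EC50 {np.exp(ln_ec50):.3g} M lies more than a decade outside "
            "the tested concentration range"
        )
    if _logistic3(np.array([x.max()]), e_max, slope_n, ln_ec50)[0] < 0.9 * e_max:
        warns.append("fitted maximum is extrapolated beyond the top tested concentration")
    if abs(slope_n - _SLOPE_BOUNDS[0]) < 1e-6 or abs(slope_n - _SLOPE_BOUNDS[1]) < 1e-6:
        warns.append("slope factor hit its bound")
    fit = Logistic3Fit(curve.ligand_id, curve.assay_id, float(e_max), float(slope_n),
                       float(ln_ec50), cov, rss, dof, tuple(warns))
    for w in warns:
        warnings.warn(f"{curve.ligand_id}/{curve.assay_id}: {w}", stacklevel=2)
    cache[key] = fit
    return fit


def fit_logistic2(curve: CRCurve, weighted: bool = False) -> Logistic2Fit:
    """Fit the 2-parameter logistic (max pinned at 1) to a reference-normalized curve."""
    cache = _fit_cache(curve)
    key = ("l2", weighted)
    if key in cache:
        return cache[key]
    _check_agonist_mode(curve)
    x, y = np.log(curve.conc), curve.resp
    if y.max() < 0.5:
        warnings.warn(
            f"{curve.ligand_id}/{curve.assay_id}: curve never reaches half of the "
            "pinned maximum 1; is it reference-normalized?", stacklevel=2,
        )
    sigma = _sigma_weights(curve, weighted)

    def residual(p):
        r = _logistic2(x, *p) - y
        return r / sigma if sigma is not None else r

    def jac(p):
        j = _logistic2_jac(x, *p)
        return j / sigma[:, None] if sigma is not None else j

    _, _, m0 = _heuristic_logistic3_start(curve)
    starts = [(m0, 1.0), (m0, 0.5), (m0, 2.0), (m0 + 2.0, 1.0), (m0 - 2.0, 1.0)]
    lo = np.array([x.min() - 30.0, _SLOPE_BOUNDS[0]])
    hi = np.array([x.max() + 30.0, _SLOPE_BOUNDS[1]])
    early = _early_cost(curve, sigma)
    try:
        res = _multistart_ls(residual, starts, (lo, hi), early_cost=early, jac=jac)
    except FitError as exc:
        raise FitError(f"{curve.ligand_id}/{curve.assay_id}: logistic2 fit failed: {exc}") from exc
    cov, rss, dof = _asymptotic_cov(res, y.size)
    fit = Logistic2Fit(curve.ligand_id, curve.assay_id, float(res.x[0]), float(res.x[1]),
                       cov, rss, dof)
    cache[key] = fit
    return fit


def fit_operational(curve: CRCurve, kd: Optional[LigandKd] = None,
                    weighted: bool = False) -> OperationalFit:
    """Fit the operational model; K_d fixed when *kd* is given, free otherwise.

    Starts are seeded from a logistic3 fit: tau and r_max are solved from the
    fitted E_max/EC50 through the operational identities, then perturbed.
    """
    cache = _fit_cache(curve)
    key = ("op", None if kd is None else kd.log_kd, weighted)
    if key in cache:
        return cache[key]
    _check_agonist_mode(curve)
    x, y = np.log(curve.conc), curve.resp
    sigma = _sigma_weights(curve, weighted)
    try:
        l3 = fit_logistic3(curve, weighted=weighted)
        e_hat, n_hat, ec50_hat = l3.e_max, min(max(l3.slope_n, 0.3), 4.0), l3.ec50
        early = 0.55 * l3.rss + 1e-16
    except FitError:
        e_hat, n_hat, ec50_hat = max(y.max(), 1e-9), 1.0, float(np.exp(np.median(x)))
        early = None

    def tau_from(kd_val: float) -> float:
        # invert EC50 = K_d / ((2 + tau^n)^(1/n) - 1) at the heuristic slope
        t_n = (kd_val / ec50_hat + 1.0) ** n_hat - 2.0
        return t_n ** (1.0 / n_hat) if t_n > 1e-6 else 0.1

    warns = []
    if kd is not None:
        lk = float(np.log(kd.kd))
        if lk < x.min() - np.log(1e3):
            warns.append(
                f"fixed K_d {kd.kd:.3g} M is more than 1000-fold below the lowest "
                "tested concentration"
            )
        tau0 = tau_from(kd.kd)
        rmax0 = e_hat * (1.0 + tau0 ** n_hat) / tau0 ** n_hat

        def residual(p):
            r = _operational(x, p[0], p[1], p[2], lk) - y
            return r / sigma if sigma is not None else r

        def jac(p):
            j = _operational_jac(x, p[0], p[1], p[2], lk, kd_free=False)
            return j / sigma[:, None] if sigma is not None else j

        lt0 = np.log(tau0)
        starts = [
            (rmax0, n_hat, lt0),
            (rmax0, 1.0, lt0), (rmax0, n_hat, lt0 + 2.0),
            (rmax0, n_hat, lt0 - 2.0), (e_hat * 1.1, n_hat, 0.0),
        ]
        lo = np.array([1e-12, _SLOPE_BOUNDS[0], _LNTAU_BOUNDS[0]])
        hi = np.array([max(y.max(), 1e-9) * 50.0, _SLOPE_BOUNDS[1], _LNTAU_BOUNDS[1]])
        try:
            res = _multistart_ls(residual, starts, (lo, hi), early_cost=early, jac=jac)
        except FitError as exc:
            raise FitError(
                f"{curve.ligand_id}/{curve.assay_id}: operational fit (K_d fixed) "
                f"failed: {exc}") from exc
        cov3, rss, dof = _asymptotic_cov(res, y.size)
        # ln_kd is a fixed input: zero-variance row/column in the 4x4 covariance
        cov = np.zeros((4, 4))
        cov[np.ix_([0, 1, 2], [0, 1, 2])] = cov3
        r_max, slope_n, ln_tau = res.x
        ln_kd = lk
        kd_fixed = True
    else:
        starts = []
        for tau0 in (0.5, 2.0, 10.0, 100.0, 1000.0):
            kd0 = ec50_hat * ((2.0 + tau0 ** n_hat) ** (1.0 / n_hat) - 1.0)
            rmax0 = e_hat * (1.0 + tau0 ** n_hat) / tau0 ** n_hat
            starts.append((rmax0, n_hat, np.log(tau0), np.log(kd0)))

        def residual(p):
            r = _operational(x, *p) - y
            return r / sigma if sigma is not None else r

        def jac(p):
            j = _operational_jac(x, *p, kd_free=True)
            return j / sigma[:, None] if sigma is not None else j

        lo = np.array([1e-12, _SLOPE_BOUNDS[0], _LNTAU_BOUNDS[0], x.min() - 35.0])
        hi = np.array([max(y.max(), 1e-9) * 50.0, _SLOPE_BOUNDS[1], _LNTAU_BOUNDS[1],
                       x.max() + 35.0])
        try:
            res = _multistart_ls(residual, starts, (lo, hi), early_cost=early, jac=jac)
        except FitError as exc:
            raise FitError(
                f"{curve.ligand_id}/{curve.assay_id}: operational fit (K_d free) "
                f"failed: {exc}") from exc
        cov, rss, dof = _asymptotic_cov(res, y.size)
        r_max, slope_n, ln_tau, ln_kd = res.x
        kd_fixed = False

    for bound, name in ((_LNTAU_BOUNDS, "ln_tau"),):
        if abs(ln_tau - bound[0]) < 1e-6 or abs(ln_tau - bound[1]) < 1e-6:
            warns.append(f"{name} hit its bound")
    fit = OperationalFit(curve.ligand_id, curve.assay_id, float(r_max), float(slope_n),
                         float(ln_tau), float(ln_kd), cov, rss, dof, kd_fixed,
                         tuple(warns))
    for w in warns:
        warnings.warn(f"{curve.ligand_id}/{curve.assay_id}: {w}", stacklevel=2)
    cache[key] = fit
    return fit


def fit_operational_panel(curves: Dict[str, CRCurve],
                          kds: "Optional[Dict[str, LigandKd]]" = None,
                          weighted: bool = False) -> Dict[str, "OperationalFit"]:
    """Global operational fit of a panel, K_d fixed per ligand or free.

    The system parameters r_max and slope n are shared across all ligands of
    the assay (they belong to the transduction machinery, not the ligand);
    each ligand contributes ln tau (K_d fixed from *kds*) or
    (ln(tau/K_d), ln K_d) when K_d is free. Sharing the system maximum is what
    identifies the per-ligand efficacy parameter for partial agonists — fitted
    independently, every curve sits on a ridge (r_max-tau with K_d fixed,
    tau-K_d with K_d free) that is only resolved in the strong-agonist limit.
    """
    ligands = list(curves)
    if kds is not None:
        missing = [l for l in ligands if l not in kds]
        if missing:
            raise ValueError(f"panel fit with fixed K_d: no K_d for {missing}")
        return _fit_operational_panel_fixed_kd(curves, kds, weighted)
    xs = {lig: np.log(curves[lig].conc) for lig in ligands}
    ys = {lig: curves[lig].resp for lig in ligands}
    sigmas = {lig: _sigma_weights(curves[lig], weighted) for lig in ligands}
    heur = {}
    y_top = 1e-9
    rss_bench = 0.0
    for lig in ligands:
        try:
            l3 = fit_logistic3(curves[lig], weighted=weighted)
            heur[lig] = (l3.e_max, l3.ec50)
            rss_bench += l3.rss
        except FitError:
            heur[lig] = (max(ys[lig].max(), 1e-9), float(np.exp(np.median(xs[lig]))))
        y_top = max(y_top, ys[lig].max())

    def unpack(p):
        r_max, n = p[0], p[1]
        per = {lig: (p[2 + 2 * i], p[3 + 2 * i]) for i, lig in enumerate(ligands)}
        return r_max, n, per

    def residual(p):
        r_max, n, per = unpack(p)
        out = []
        for lig in ligands:
            lr, lk = per[lig]
            x = xs[lig]
            # E = r_max / (1 + exp(n ln(L/K_d + 1) - n (ln R + ln L))), R = tau/K_d
            z = n * np.logaddexp(x - lk, 0.0) - n * (lr + x)
            r = r_max / (1.0 + np.exp(np.clip(z, -500, 500))) - ys[lig]
            s = sigmas[lig]
            out.append(r / s if s is not None else r)
        return np.concatenate(out)

    def jac(p):
        r_max, n, per = unpack(p)
        n_obs_all = sum(x.size for x in xs.values())
        out = np.zeros((n_obs_all, p.size))
        row = 0
        for i, lig in enumerate(ligands):
            lr, lk = per[lig]
            x = xs[lig]
            a = np.logaddexp(x - lk, 0.0)
            z = np.clip(n * a - n * (lr + x), -500, 500)
            sig = 1.0 / (1.0 + np.exp(z))
            dz = -r_max * sig * (1.0 - sig)
            rows = slice(row, row + x.size)
            out[rows, 0] = sig
            out[rows, 1] = dz * (a - lr - x)
            out[rows, 2 + 2 * i] = dz * (-n)
            out[rows, 3 + 2 * i] = dz * (-n / (1.0 + np.exp(np.clip(lk - x, -500, 500))))
            s = sigmas[lig]
            if s is not None:
                out[rows, :] /= s[:, None]
            row += x.size
        return out

    rmax0 = max(e for e, _ in heur.values()) * 1.02
    x_all = np.concatenate(list(xs.values()))
    p0 = [rmax0, 1.0]
    lo = [1e-12, _SLOPE_BOUNDS[0]]
    hi = [y_top * 20.0, _SLOPE_BOUNDS[1]]
    for lig in ligands:
        e_hat, ec50_hat = heur[lig]
        if e_hat < 0.95 * rmax0:
            tau0 = max(e_hat / max(rmax0 - e_hat, 1e-6), 1e-3)
            kd0 = ec50_hat * (1.0 + tau0)
            r0 = tau0 / kd0
        else:
            kd0 = 100.0 * ec50_hat
            r0 = 1.0 / ec50_hat
        p0 += [np.log(r0), np.log(kd0)]
        lo += [-x_all.max() - 35.0, x_all.min() - 20.0]
        hi += [-x_all.min() + 35.0, x_all.max() + 35.0]
    starts = [np.array(p0)]
    for n0 in (0.7, 1.5):
        alt = np.array(p0)
        alt[1] = n0
        starts.append(alt)
    n_obs = sum(y.size for y in ys.values())
    try:
        res = _multistart_ls(residual, starts, (np.array(lo), np.array(hi)),
                             early_cost=0.55 * rss_bench + 1e-14, jac=jac)
    except FitError as exc:
        raise FitError(f"global operational panel fit failed: {exc}") from exc
    cov_full, rss, dof = _asymptotic_cov(res, n_obs)
    r_max, n, per = unpack(res.x)
    fits = {}
    for i, lig in enumerate(ligands):
        lr, lk = per[lig]
        idx = [0, 1, 2 + 2 * i, 3 + 2 * i]
        sub = cov_full[np.ix_(idx, idx)]
        # reparameterize (r_max, n, ln R, ln K_d) -> (r_max, n, ln tau, ln K_d)
        t_mat = np.array([[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 1], [0, 0, 0, 1]], float)
        cov = t_mat @ sub @ t_mat.T
        fits[lig] = OperationalFit(
            lig, curves[lig].assay_id, float(r_max), float(n),
            float(lr + lk), float(lk), cov, rss, dof, kd_fixed=False,
        )
    return fits


def _fit_operational_panel_fixed_kd(curves: Dict[str, CRCurve],
                                    kds: Dict[str, LigandKd],
                                    weighted: bool) -> Dict[str, "OperationalFit"]:
    ligands = list(curves)
    xs = {lig: np.log(curves[lig].conc) for lig in ligands}
    ys = {lig: curves[lig].resp for lig in ligands}
    lks = {lig: float(np.log(kds[lig].kd)) for lig in ligands}
    sigmas = {lig: _sigma_weights(curves[lig], weighted) for lig in ligands}
    heur = {}
    y_top = 1e-9
    rss_bench = 0.0
    for lig in ligands:
        try:
            l3 = fit_logistic3(curves[lig], weighted=weighted)
            heur[lig] = (l3.e_max, l3.ec50)
            rss_bench += l3.rss
        except FitError:
            heur[lig] = (max(ys[lig].max(), 1e-9), float(np.exp(np.median(xs[lig]))))
        y_top = max(y_top, ys[lig].max())

    def unpack(p):
        return p[0], p[1], {lig: p[2 + i] for i, lig in enumerate(ligands)}

    def residual(p):
        r_max, n, per = unpack(p)
        out = []
        for lig in ligands:
            r = _operational(xs[lig], r_max, n, per[lig], lks[lig]) - ys[lig]
            s = sigmas[lig]
            out.append(r / s if s is not None else r)
        return np.concatenate(out)

    def jac(p):
        r_max, n, per = unpack(p)
        n_obs_all = sum(x.size for x in xs.values())
        out = np.zeros((n_obs_all, p.size))
        row = 0
        for i, lig in enumerate(ligands):
            x = xs[lig]
            j = _operational_jac(x, r_max, n, per[lig], lks[lig], kd_free=False)
            s = sigmas[lig]
            if s is not None:
                j = j / s[:, None]
            rows = slice(row, row + x.size)
            out[rows, 0] = j[:, 0]
            out[rows, 1] = j[:, 1]
            out[rows, 2 + i] = j[:, 2]
            row += x.size
        return out

    rmax0 = max(e for e, _ in heur.values()) * 1.02
    p0 = [rmax0, 1.0]
    lo = [1e-12, _SLOPE_BOUNDS[0]]
    hi = [y_top * 20.0, _SLOPE_BOUNDS[1]]
    for lig in ligands:
        e_hat, ec50_hat = heur[lig]
        if e_hat < 0.95 * rmax0:
            tau0 = max(e_hat / max(rmax0 - e_hat, 1e-6), 1e-3)
        else:
            tau0 = max(np.exp(lks[lig]) / ec50_hat - 1.0, 1.0)
        p0.append(np.clip(np.log(tau0), _LNTAU_BOUNDS[0] + 1e-6,
                          _LNTAU_BOUNDS[1] - 1e-6))
        lo.append(_LNTAU_BOUNDS[0])
        hi.append(_LNTAU_BOUNDS[1])
    starts = [np.array(p0)]
    for n0 in (0.7, 1.5):
        alt = np.array(p0)
        alt[1] = n0
        starts.append(alt)
    n_obs = sum(y.size for y in ys.values())
    try:
        res = _multistart_ls(residual, starts, (np.array(lo), np.array(hi)),
                             early_cost=0.55 * rss_bench + 1e-14, jac=jac)
    except FitError as exc:
        raise FitError(f"global operational panel fit (K_d fixed) failed: {exc}") from exc
    cov_full, rss, dof = _asymptotic_cov(res, n_obs)
    r_max, n, per = unpack(res.x)
    fits = {}
    for i, lig in enumerate(ligands):
        idx = [0, 1, 2 + i]
        sub = cov_full[np.ix_(idx, idx)]
        cov = np.zeros((4, 4))
        cov[np.ix_([0, 1, 2], [0, 1, 2])] = sub
        fits[lig] = OperationalFit(
            lig, curves[lig].assay_id, float(r_max), float(n),
            float(per[lig]), lks[lig], cov, rss, dof, kd_fixed=True,
        )
    return fits


def inverse_response(fit: Logistic3Fit, level: float) -> float:
    """Concentration at which the fitted 3-parameter logistic equals *level*.

    Closed form of the logistic inverse: [L] = EC50 * (E_max/level - 1)^(-1/n).
    """
    if not (0.0 < level < fit.e_max):
        raise ValueError(
            f"{fit.ligand_id}/{fit.assay_id}: response level {level:.4g} is outside "
            f"(0, E_max={fit.e_max:.4g}); equi-effective concentration undefined"
        )
    return float(fit.ec50 * (fit.e_max / level - 1.0) ** (-1.0 / fit.slope_n))
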