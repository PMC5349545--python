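"""Model-free bias diagnostics from intrinsic activities: methods 8 and 9.

Both methods compare the intrinsic activities (IA) of a panel of agonists
between two assays against the *reference trajectory*: the curve traced in the
plane of the two normalized responses by the full reference agonist's CR
curves. System bias bends this trajectory but — being a monotone map — cannot
change the IA rank order of unbiased ligands; ligand bias can.

Method 8 re-maps observed and trajectory-projected points to rank space and
asks, via Monte Carlo perturbation of the projected points with the ligands'
own experimental SDs, whether an observed rank pair falls outside the 95%
joint confidence contour of its null distribution. Method 9 tests whether the
95% confidence ellipse of an observed IA pair intersects the ellipse of its
projection on the trajectory; it works down to a single test ligand. Neither
method quantifies the magnitude of bias — outputs are categorical flags plus
distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
from scipy import optimize, stats

from .curve_fitting import FitError, Logistic2Fit, fit_logistic2, fit_logistic3
from .data_model import AssayPanel, CRCurve, IntrinsicActivity

__all__ = [
    "ReferenceTrajectory",
    "ProjectedPoint",
    "RankOrderResult",
    "Ellipse",
    "EllipseTestResult",
    "build_trajectory",
    "project_point",
    "method8_rank_order",
    "method9_distance",
    "ellipses_intersect",
    "panel_intrinsic_activities",
]

_EDGE = 1e-300  # trajectory parameter kept strictly inside (0, 1)
_GRID_EDGE = 1e-9  # practical bounds for projection searches


def panel_intrinsic_activities(panel: AssayPanel,
                               weighted: bool = False) -> Dict[str, IntrinsicActivity]:
    """Fitted maxima (with asymptotic SE) of every curve in a normalized panel."""
    out = {}
    for lig, curve in panel.curves.items():
        try:
            fit = fit_logistic3(curve, weighted=weighted)
        except FitError as exc:
            warnings.warn(f"intrinsic activity of {lig!r} unavailable: {exc}",
                          stacklevel=2)
            continue
        out[lig] = IntrinsicActivity(lig, panel.assay_id, fit.e_max, fit.e_max_se)
    return out


# ---------------------------------------------------------------------------
# reference trajectory
# ---------------------------------------------------------------------------

@dataclass
class ReferenceTrajectory:
    """Y' as a function of Y for the reference agonist across two assays.

    Eliminating [L] between the two 2-parameter logistics with midpoints c, c'
    and slopes b, b' gives the closed form

        Y'(Y) = 1 / (1 + (c'/c)^b' * ((1-Y)/Y)^(b'/b))

    which runs monotonically from (0, 0) to (1, 1). The pointwise confidence
    band is propagated from the two regressions' asymptotic covariances by the
    delta method.
    """

    fit_a: Logistic2Fit
    fit_b: Logistic2Fit

    def _zeta(self, y: np.ndarray, swap: bool = False) -> np.ndarray:
        fa, fb = (self.fit_b, self.fit_a) if swap else (self.fit_a, self.fit_b)
        u = np.log((1.0 - y) / y)
        return fb.slope_b * (fb.ln_c - fa.ln_c) + (fb.slope_b / fa.slope_b) * u

    def curve(self, y: np.ndarray | float) -> np.ndarray:
        """Trajectory ordinate Y'(Y)."""
        y = np.clip(np.asarray(y, dtype=float), _EDGE, 1.0 - _EDGE)
        return 1.0 / (1.0 + np.exp(np.clip(self._zeta(y), -500, 500)))

    def inverse(self, yp: np.ndarray | float) -> np.ndarray:
        """Trajectory abscissa Y(Y') — the same elimination with roles swapped."""
        yp = np.clip(np.asarray(yp, dtype=float), _EDGE, 1.0 - _EDGE)
        return 1.0 / (1.0 + np.exp(np.clip(self._zeta(yp, swap=True), -500, 500)))

    def _se(self, y: np.ndarray, swap: bool) -> np.ndarray:
        """Delta-method SE of the trajectory ordinate at fixed abscissa."""
        fa, fb = (self.fit_b, self.fit_a) if swap else (self.fit_a, self.fit_b)
        y = np.clip(np.asarray(y, dtype=float), _EDGE, 1.0 - _EDGE)
        u = np.log((1.0 - y) / y)
        z = fb.slope_b * (fb.ln_c - fa.ln_c) + (fb.slope_b / fa.slope_b) * u
        yp = 1.0 / (1.0 + np.exp(np.clip(z, -500, 500)))
        dy = -yp * (1.0 - yp)  # dY'/dzeta
        # zeta gradients wrt (m_a, b_a, m_b, b_b) with m = ln c
        g_ma = -fb.slope_b * np.ones_like(u)
        g_ba = -(fb.slope_b / fa.slope_b ** 2) * u
        g_mb = fb.slope_b * np.ones_like(u)
        g_bb = (fb.ln_c - fa.ln_c) + u / fa.slope_b
        ca, cb = fa.cov, fb.cov
        var_z = (
            g_ma ** 2 * ca[0, 0] + 2 * g_ma * g_ba * ca[0, 1] + g_ba ** 2 * ca[1, 1]
            + g_mb ** 2 * cb[0, 0] + 2 * g_mb * g_bb * cb[0, 1] + g_bb ** 2 * cb[1, 1]
        )
        return np.abs(dy) * np.sqrt(np.maximum(var_z, 0.0))

    @property
    def dof(self) -> int:
        return self.fit_a.dof + self.fit_b.dof

    def band(self, y: np.ndarray | float, level: float = 0.95):
        """Pointwise confidence band (lo, hi) of Y'(Y)."""
        t = stats.t.ppf(0.5 + level / 2.0, self.dof)
        yp = self.curve(y)
        half = t * self._se(np.asarray(y, float), swap=False)
        return yp - half, yp + half

    def halfwidths_at(self, y: float, level: float = 0.95) -> Tuple[float, float]:
        """Band half-widths along the x and y axes at trajectory point Y=y."""
        t = stats.t.ppf(0.5 + level / 2.0, self.dof)
        hw_y = t * float(self._se(np.asarray([y]), swap=False)[0])
        yp = float(self.curve(y))
        hw_x = t * float(self._se(np.asarray([yp]), swap=True)[0])
        return hw_x, hw_y

    def swapped(self) -> "ReferenceTrajectory":
        return ReferenceTrajectory(self.fit_b, self.fit_a)


def build_trajectory(ref_curve_a: CRCurve, ref_curve_b: CRCurve,
                     weighted: bool = False) -> ReferenceTrajectory:
    """Fit the reference agonist in both assays and return its trajectory."""
    if ref_curve_a.ligand_id != ref_curve_b.ligand_id:
        raise ValueError(
            "trajectory requires the same (reference) ligand in both assays, got "
            f"{ref_curve_a.ligand_id!r} and {ref_curve_b.ligand_id!r}"
        )
    fit_a = fit_logistic2(ref_curve_a, weighted=weighted)
    fit_b = fit_logistic2(ref_curve_b, weighted=weighted)
    return ReferenceTrajectory(fit_a, fit_b)


# ---------------------------------------------------------------------------
# anisotropic projection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProjectedPoint:
    """Observed IA pair and its nearest trajectory point under the
    inverse-variance-weighted metric."""

    ligand_id: str
    observed: Tuple[float, float]
    sd: Tuple[float, float]
    projected: Tuple[float, float]
    distance: float  # minimized metric value (in SD units)


def project_point(ia_a: IntrinsicActivity, ia_b: IntrinsicActivity,
                  traj: ReferenceTrajectory) -> ProjectedPoint:
    """Project an observed IA pair onto the trajectory.

    Minimizes d^2(Y) = (Y - ia_A)^2/sd_A^2 + (Y'(Y) - ia_B)^2/sd_B^2 over
    Y in (0, 1): displacements along each axis are weighted with the inverse
    variance of the experimental error. A coarse grid locates the basin, then
    bounded 1-D optimization refines it.
    """
    if ia_a.ia_sd <= 0 or ia_b.ia_sd <= 0:
        raise ValueError(
            f"{ia_a.ligand_id!r}: projection needs positive IA uncertainties on "
            "both axes; supply ia_sd > 0"
        )
    xa, xb = ia_a.ia, ia_b.ia
    sa, sb = ia_a.ia_sd, ia_b.ia_sd

    def d2(y):
        return ((y - xa) / sa) ** 2 + ((traj.curve(y) - xb) / sb) ** 2

    grid = np.linspace(_GRID_EDGE, 1.0 - _GRID_EDGE, 512)
    vals = d2(grid)
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = optimize.minimize_scalar(d2, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-12})
    y_star = float(res.x) if res.fun <= vals[i] else float(grid[i])
    return ProjectedPoint(
        ia_a.ligand_id, (xa, xb), (sa, sb),
        (y_star, float(traj.curve(y_star))), float(np.sqrt(min(res.fun, vals[i]))),
    )


# ---------------------------------------------------------------------------
# method 8: rank-order Monte Carlo
# ---------------------------------------------------------------------------

@dataclass
class RankOrderResult:
    """Joint rank distributions, the 95% contour and flags of the rank-order test.

    ``joint_density`` keeps the per-ligand-position frequencies (each slice
    sums to 1); ``contour95`` is the highest-density 95% envelope of the
    *pooled* joint density — one contour per comparison, as a band about the
    identity diagonal — against which every observed rank pair is tested.
    """

    ligands: Tuple[str, ...]
    observed_ranks: Dict[str, Tuple[int, int]]
    joint_density: np.ndarray  # (ligand, rank_A, rank_B), slices sum to 1
    contour95: Set[Tuple[int, int]]
    flagged: Tuple[str, ...]
    projections: Tuple[ProjectedPoint, ...] = field(default_factory=tuple)

    @property
    def pooled_density(self) -> np.ndarray:
        return self.joint_density.mean(axis=0)


def _stable_ranks(values: np.ndarray) -> np.ndarray:
    """1-based ranks; ties broken by position (stable ligand-id order)."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(values.size, dtype=int)
    ranks[order] = np.arange(1, values.size + 1)
    return ranks


def _batch_ranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, axis=1, kind="stable")
    ranks = np.empty_like(order)
    n = values.shape[1]
    rows = np.arange(values.shape[0])[:, None]
    ranks[rows, order] = np.arange(1, n + 1)[None, :]
    return ranks


def _hdr_contour(freq: np.ndarray, mass: float = 0.95) -> Set[Tuple[int, int]]:
    """Highest-density region on the integer rank lattice covering >= mass."""
    flat = freq.ravel()
    order = np.argsort(flat)[::-1]
    cum = np.cumsum(flat[order])
    k = int(np.searchsorted(cum, mass * flat.sum() - 1e-12)) + 1
    cells = set()
    n = freq.shape[1]
    for idx in order[:k]:
        if flat[idx] <= 0:
            break
        cells.add((idx // n + 1, idx % n + 1))
    return cells


def method8_rank_order(ias_a: Sequence[IntrinsicActivity],
                       ias_b: Sequence[IntrinsicActivity],
                       traj: ReferenceTrajectory,
                       n_mc: int = 500_000, seed: int = 0) -> RankOrderResult:
    """Rank-order bias test (method 8).

    Projects every ligand's IA pair onto the reference trajectory (projected
    ranks trace the identity line), perturbs the projected coordinates with
    each ligand's own SDs over *n_mc* Monte Carlo iterations, accumulates the
    joint rank frequencies, and flags ligands whose observed rank pair lies
    outside the 95% highest-density envelope of the pooled joint distribution.
    Deterministic per seed.
    """
    if n_mc < 1000:
        raise ValueError("n_mc < 1000 cannot resolve a 95% contour; refused")
    by_id_a = {ia.ligand_id: ia for ia in ias_a}
    by_id_b = {ia.ligand_id: ia for ia in ias_b}
    ligands = tuple(sorted(set(by_id_a) & set(by_id_b)))
    n = len(ligands)
    if n < 6:
        warnings.warn(
            "rank-order diagnostics needs a reasonably large panel of mostly "
            f"unbiased ligands; only {n} shared ligands supplied", stacklevel=2,
        )
    projections = tuple(
        project_point(by_id_a[l], by_id_b[l], traj) for l in ligands
    )
    obs_x = np.array([by_id_a[l].ia for l in ligands])
    obs_y = np.array([by_id_b[l].ia for l in ligands])
    sd_x = np.array([by_id_a[l].ia_sd for l in ligands])
    sd_y = np.array([by_id_b[l].ia_sd for l in ligands])
    proj_x = np.array([p.projected[0] for p in projections])
    proj_y = np.array([p.projected[1] for p in projections])

    ranks_a = _stable_ranks(obs_x)
    ranks_b = _stable_ranks(obs_y)
    observed_ranks = {l: (int(ra), int(rb)) for l, ra, rb in zip(ligands, ranks_a, ranks_b)}

    rng = np.random.default_rng(seed)
    counts = np.zeros((n, n, n), dtype=np.int64)
    chunk = 100_000
    done = 0
    lig_idx = np.arange(n)
    while done < n_mc:
        m = min(chunk, n_mc - done)
        px = proj_x[None, :] + rng.standard_normal((m, n)) * sd_x[None, :]
        py = proj_y[None, :] + rng.standard_normal((m, n)) * sd_y[None, :]
        ra = _batch_ranks(px) - 1
        rb = _batch_ranks(py) - 1
        for i in lig_idx:
            np.add.at(counts[i], (ra[:, i], rb[:, i]), 1)
        done += m
    joint_density = counts / float(n_mc)

    contour95 = _hdr_contour(joint_density.mean(axis=0))
    flagged = tuple(l for l in ligands if observed_ranks[l] not in contour95)
    return RankOrderResult(ligands, observed_ranks, joint_density, contour95,
                           flagged, projections)


# ---------------------------------------------------------------------------
# method 9: trajectory-distance test with confidence ellipses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Ellipse:
    """An ellipse: center, semi-axes and orientation (radians, CCW from x)."""

    cx: float
    cy: float
    a: float
    b: float
    angle: float = 0.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("ellipse semi-axes must be positive")

    def boundary(self, t: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        ct, st = np.cos(self.angle), np.sin(self.angle)
        ex, ey = self.a * np.cos(t), self.b * np.sin(t)
        return self.cx + ct * ex - st * ey, self.cy + st * ex + ct * ey

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        ct, st = np.cos(self.angle), np.sin(self.angle)
        dx, dy = np.asarray(x) - self.cx, np.asarray(y) - self.cy
        u = (ct * dx + st * dy) / self.a
        v = (-st * dx + ct * dy) / self.b
        return u ** 2 + v ** 2 <= 1.0


def ellipses_intersect(e1: Ellipse, e2: Ellipse) -> bool:
    """Exact-to-tolerance intersection test (boundaries or interiors overlap).

    e1 is affinely mapped to the unit circle; e2's image under that map is an
    ellipse whose minimum distance from the origin is found by 1-D optimization
    over its boundary parameter (multi-start on a coarse grid). The figures
    overlap iff that minimum is <= 1 or either center lies inside the other.
    """
    # affine map: rotate by -angle1, scale by (1/a1, 1/b1)
    c1, s1 = np.cos(e1.angle), np.sin(e1.angle)

    def to_circle(x, y):
        dx, dy = x - e1.cx, y - e1.cy
        return (c1 * dx + s1 * dy) / e1.a, (-s1 * dx + c1 * dy) / e1.b

    if e2.contains(np.array(e1.cx), np.array(e1.cy)) or e1.contains(
            np.array(e2.cx), np.array(e2.cy)):
        return True

    def norm2(t):
        bx, by = e2.boundary(np.asarray(t))
        u, v = to_circle(bx, by)
        return u ** 2 + v ** 2

    tgrid = np.linspace(0.0, 2.0 * np.pi, 361)
    vals = norm2(tgrid)
    i = int(np.argmin(vals))
    lo, hi = tgrid[max(i - 1, 0)], tgrid[min(i + 1, tgrid.size - 1)]
    res = optimize.minimize_scalar(norm2, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-12})
    return float(min(res.fun, vals[i])) <= 1.0


@dataclass(frozen=True)
class EllipseTestResult:
    """Outcome of the trajectory-distance test for one ligand."""

    ligand_id: str
    projection: ProjectedPoint
    ellipse_obs: Ellipse
    ellipse_proj: Ellipse
    intersects: bool
    flagged: bool
    warnings: Tuple[str, ...] = field(default_factory=tuple)


def method9_distance(ias_a: Sequence[IntrinsicActivity],
                     ias_b: Sequence[IntrinsicActivity],
                     traj: ReferenceTrajectory,
                     ellipse_df: int = 2) -> List[EllipseTestResult]:
    """Trajectory-distance bias test (method 9).

    Each ligand's observed IA pair gets an axis-aligned 95% ellipse from its
    experimental SDs (axes scaled by sqrt(chi2_{df=2, 0.95}) by default, or the
    1-df normal quantile with ``ellipse_df=1``); its projection on the
    trajectory gets an ellipse from the propagated trajectory band half-widths.
    A ligand is called biased when the two ellipses are disjoint. Applicable to
    a single test ligand.
    """
    if ellipse_df == 2:
        radius = float(np.sqrt(stats.chi2.ppf(0.95, 2)))
    elif ellipse_df == 1:
        radius = float(stats.norm.ppf(0.975))
    else:
        raise ValueError("ellipse_df must be 1 or 2")
    by_id_b = {ia.ligand_id: ia for ia in ias_b}
    results = []
    for ia_a in ias_a:
        if ia_a.ligand_id not in by_id_b:
            continue
        ia_b = by_id_b[ia_a.ligand_id]
        proj = project_point(ia_a, ia_b, traj)
        warns: List[str] = []
        y0 = proj.projected[0]
        if y0 < 1e-4 or y0 > 1.0 - 1e-4:
            warns.append(
                "projected point sits at the trajectory boundary; the confidence "
                "band is undefined at the extremes"
            )
            warnings.warn(f"{ia_a.ligand_id!r}: {warns[-1]}", stacklevel=2)
        hw_x, hw_y = traj.halfwidths_at(min(max(y0, 1e-4), 1.0 - 1e-4))
        obs = Ellipse(proj.observed[0], proj.observed[1],
                      radius * proj.sd[0], radius * proj.sd[1])
        prj = Ellipse(proj.projected[0], proj.projected[1],
                      max(hw_x, 1e-12), max(hw_y, 1e-12))
        hit = ellipses_intersect(obs, prj)
        results.append(EllipseTestResult(ia_a.ligand_id, proj, obs, prj, hit,
                                         not hit, tuple(warns)))
    return results
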