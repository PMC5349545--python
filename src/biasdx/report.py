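"""Run configuration and the side-by-side method comparison report.

``run_all_methods`` runs every requested diagnostic on one assay pair and
assembles a per-ligand × per-method table, per-method summary indicators
(RMS deviation from zero bias, positive-hit rate), and the inter-method
Pearson correlation matrix of bias factors — the package's analogue of a
published method-comparison table. Every run carries a provenance block
(config hash, seed, package version) so stochastic results are regenerable
bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_model import AssayPanel, BiasResult, LigandKd
from .model_based import (
    COMMON_RANGE,
    N_LEVELS,
    OPTIMIZED_RANGE,
    SINGLE_LEVEL_FRACTION,
    SLOPE_WARN_THRESHOLD,
    MethodSummary,
    apply_null_band,
    bias_method1,
    bias_method2,
    bias_method3,
    bias_method7,
    bias_methods456,
    monte_carlo_null_band,
    summarize_methods,
)
from .model_free import (
    EllipseTestResult,
    RankOrderResult,
    build_trajectory,
    method8_rank_order,
    method9_distance,
    panel_intrinsic_activities,
)

__all__ = ["RunConfig", "BiasReport", "run_all_methods", "results_to_frame"]

log = logging.getLogger("biasdx")


@dataclass
class RunConfig:
    """All tunables of a diagnostic run, with their documented defaults."""

    methods: Tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 9)
    # level-selection (methods 4-6)
    single_level_fraction: float = SINGLE_LEVEL_FRACTION
    common_range: Tuple[float, float] = COMMON_RANGE
    optimized_range: Tuple[float, float] = OPTIMIZED_RANGE
    n_levels: int = N_LEVELS
    slope_warn: float = SLOPE_WARN_THRESHOLD
    # Monte Carlo null band (methods 1-7)
    n_sim: int = 500
    per_ligand_band: bool = False
    # rank-order Monte Carlo (method 8)
    n_mc: int = 500_000
    # ellipse quantile convention (method 9): 2-df chi-square or 1-df normal
    ellipse_df: int = 2
    # inverse-variance weighting of the regressions
    weighted: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(open(path)) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("methods",):
            if key in raw:
                raw[key] = tuple(raw[key])
        for key in ("common_range", "optimized_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class BiasReport:
    """Everything one comparison run produced."""

    table: pd.DataFrame
    summaries: Dict[int, MethodSummary]
    correlation: pd.DataFrame
    rank_order: Optional[RankOrderResult]
    ellipse_tests: Optional[List[EllipseTestResult]]
    provenance: Dict[str, object]

    def to_json(self) -> str:
        out = {
            "provenance": self.provenance,
            "summaries": {
                m: {"rms_deviation": s.rms_deviation, "hit_rate": s.hit_rate,
                    "n_ligands": s.n_ligands, "n_comparisons": s.n_comparisons}
                for m, s in self.summaries.items()
            },
            "correlation": json.loads(self.correlation.to_json()),
            "flagged": {
                "rank_order": list(self.rank_order.flagged) if self.rank_order else None,
                "ellipse": [r.ligand_id for r in self.ellipse_tests if r.flagged]
                if self.ellipse_tests else None,
            },
        }
        return json.dumps(out, indent=2, sort_keys=True, default=float)


def results_to_frame(results: Sequence[BiasResult]) -> pd.DataFrame:
    """Flatten BiasResults to the canonical output table."""
    rows = [
        {
            "ligand": r.ligand_id,
            "method": r.method_id,
            "assay_a": r.assay_pair[0],
            "assay_b": r.assay_pair[1],
            "bias_factor": r.bias_factor,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "flagged": r.flagged,
            "warnings": "; ".join(r.warnings),
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def _method_correlations(table: pd.DataFrame, reference: str) -> pd.DataFrame:
    """Pearson correlations between methods over pooled (ligand, comparison) rows.

    Zero-variance columns (e.g. a duplicate-panel run where every bias factor
    is 0) yield NaN entries, reported as such.
    """
    sub = table[(table["ligand"] != reference) & table["bias_factor"].notna()]
    wide = sub.pivot_table(index=["ligand", "assay_a", "assay_b"], columns="method",
                           values="bias_factor")
    with np.errstate(divide="ignore", invalid="ignore"):
        return wide.corr(method="pearson")


def run_all_methods(panel_a: AssayPanel, panel_b: AssayPanel,
                    kds: Optional[Dict[str, LigandKd]] = None,
                    cfg: Optional[RunConfig] = None) -> BiasReport:
    """Run the requested diagnostics on one assay pair and assemble the report."""
    cfg = cfg or RunConfig()
    if panel_a.reference_ligand != panel_b.reference_ligand:
        raise ValueError("panels carry different reference ligands")
    ref = panel_a.reference_ligand

    all_results: List[BiasResult] = []
    summaries: Dict[int, MethodSummary] = {}
    for method_id in sorted(set(cfg.methods) & {1, 2, 3, 4, 5, 6, 7}):
        if method_id in (1, 4, 5, 6) and not kds:
            log.info("method %d skipped: requires a K_d table and none was given",
                     method_id)
            continue
        if method_id == 1:
            results = bias_method1(panel_a, panel_b, kds, cfg.weighted)
        elif method_id == 2:
            results = bias_method2(panel_a, panel_b, cfg.weighted)
        elif method_id == 3:
            results = bias_method3(panel_a, panel_b, cfg.weighted, cfg.slope_warn)
        elif method_id in (4, 5, 6):
            strategy = {4: "single_level", 5: "common_range", 6: "optimized_range"}[method_id]
            results = bias_methods456(
                panel_a, panel_b, kds, strategy, cfg.weighted,
                cfg.single_level_fraction, cfg.common_range, cfg.optimized_range,
                cfg.n_levels,
            )
        else:
            results = bias_method7(panel_a, panel_b, cfg.n_levels, cfg.weighted)
        band = monte_carlo_null_band(
            panel_a, panel_b, method_id, n_sim=cfg.n_sim,
            seed=cfg.seed + method_id, kds=kds, per_ligand=cfg.per_ligand_band,
        )
        if cfg.per_ligand_band:
            from dataclasses import replace
            flagged = []
            for r in results:
                lo, hi = band.get(r.ligand_id, (None, None))
                is_hit = (
                    lo is not None and r.bias_factor is not None
                    and not (lo <= r.bias_factor <= hi)
                )
                flagged.append(replace(r, ci_low=lo, ci_high=hi, flagged=is_hit))
            results = flagged
        else:
            results = apply_null_band(results, band)
        for r in results:
            if r.warnings:
                log.info("method %d, ligand %s: %s", method_id, r.ligand_id,
                         "; ".join(r.warnings))
        all_results.extend(results)
        summaries[method_id] = summarize_methods(results, reference_ligand=ref)

    rank_order = None
    ellipse_tests = None
    if {8, 9} & set(cfg.methods):
        traj = build_trajectory(panel_a.reference_curve, panel_b.reference_curve,
                                cfg.weighted)
        ias_a = panel_intrinsic_activities(panel_a, cfg.weighted)
        ias_b = panel_intrinsic_activities(panel_b, cfg.weighted)
        shared = [l for l in ias_a if l in ias_b and l != ref]
        pair = (panel_a.assay_id, panel_b.assay_id)
        if 8 in cfg.methods:
            rank_order = method8_rank_order(
                [ias_a[l] for l in shared], [ias_b[l] for l in shared], traj,
                n_mc=cfg.n_mc, seed=cfg.seed + 8,
            )
            res8 = [
                BiasResult(l, 8, pair, None, flagged=l in rank_order.flagged)
                for l in shared
            ]
            all_results.extend(res8)
            summaries[8] = summarize_methods(res8, reference_ligand=ref)
        if 9 in cfg.methods:
            ellipse_tests = method9_distance(
                [ias_a[l] for l in shared], [ias_b[l] for l in shared], traj,
                cfg.ellipse_df,
            )
            res9 = [
                BiasResult(r.ligand_id, 9, pair, None, flagged=r.flagged,
                           warnings=r.warnings)
                for r in ellipse_tests
            ]
            all_results.extend(res9)
            summaries[9] = summarize_methods(res9, reference_ligand=ref)

    table = results_to_frame(all_results)
    correlation = _method_correlations(table, ref)
    provenance = {
        "package": "biasdx",
        "version": __version__,
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "assay_pair": [panel_a.assay_id, panel_b.assay_id],
        "reference_ligand": ref,
    }
    return BiasReport(table, summaries, correlation, rank_order, ellipse_tests,
                      provenance)
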