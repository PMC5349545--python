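"""Synthetic concentration-response panels: system bias without ligand bias.

The generator emulates a panel of agonists with graded intrinsic efficacies
observed through two different saturating transfer functions — the canonical
negative-control construct for bias diagnostics. Mechanism, per ligand and
pathway:

    occupancy   O([L]) = [L] / ([L] + K_d)
    stimulus    s      = epsilon * bias * O
    response    r      = f(s)       (pathway-specific transfer function)

with f hyperbolic, f(s) = r_max s^n / (K_E^n + s^n), so that the generated
curves satisfy the operational model exactly (tau = epsilon/K_E) and methods
that assume it are well-specified. A logarithmic transfer (monotone but
non-saturating) is available to emulate realistic model misspecification.

Replicate noise is additive Gaussian on the normalized response; curves store
the mean across replicates and, as ``resp_sd``, the standard deviation of that
mean (noise_sd / sqrt(n_replicates)). Efficacies are shared between pathways
unless a ``bias_map`` entry injects a multiplicative perturbation in pathway B
— the ground truth against which the diagnostics are scored.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .data_model import (
    AssayPanel,
    CRCurve,
    LigandKd,
    normalize_panel,
    write_ia_csv,
    write_kd_csv,
    write_panel_csv,
)

__all__ = ["TransferFunction", "SimConfig", "simulate_panels", "make_fixture_suite"]


@dataclass(frozen=True)
class TransferFunction:
    """Monotone stimulus-to-response map of one signalling pathway."""

    r_max: float = 1.0
    k_e: float = 0.3      # sensitivity: stimulus giving half-maximal response
    slope_n: float = 1.0
    family: str = "hyperbolic"  # or "log" (non-saturating, misspecified on purpose)

    def __call__(self, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        if self.family == "hyperbolic":
            sn = s ** self.slope_n
            return self.r_max * sn / (self.k_e ** self.slope_n + sn)
        if self.family == "log":
            return self.r_max * np.log1p(s / self.k_e)
        raise ValueError(f"unknown transfer family {self.family!r}")


def _default_efficacies(n: int) -> Tuple[float, ...]:
    # reference at 1.0, test ligands spanning 0.05..0.95 geometrically
    return (1.0, *np.geomspace(0.05, 0.95, n - 1).round(6).tolist())


def _default_kds(n: int) -> Tuple[float, ...]:
    return tuple(np.geomspace(1e-7, 1e-5, n).round(12).tolist())


@dataclass
class SimConfig:
    """Study conditions for one simulated two-pathway experiment.

    Defaults are a desk-scale panel: 12 ligands (reference = the full agonist,
    efficacy 1), 10 log-spaced concentrations, 3 replicates, Gaussian replicate
    noise of SD 0.02 on the normalized response, and two hyperbolic transfer
    functions differing 10-fold in sensitivity (strong system bias, no ligand
    bias unless ``bias_map`` says otherwise).
    """

    n_ligands: int = 12
    efficacy_grid: Tuple[float, ...] = None  # type: ignore[assignment]
    kd_grid: Tuple[float, ...] = None        # type: ignore[assignment]
    transfer_a: TransferFunction = field(default_factory=lambda: TransferFunction(k_e=0.1))
    transfer_b: TransferFunction = field(default_factory=lambda: TransferFunction(k_e=1.0))
    bias_map: Dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.02
    conc_grid: Tuple[float, ...] = tuple(np.geomspace(1e-11, 1e-3, 10).tolist())
    n_replicates: int = 3
    seed: int = 0
    assay_a: str = "assayA"
    assay_b: str = "assayB"

    def __post_init__(self) -> None:
        if self.efficacy_grid is None:
            self.efficacy_grid = _default_efficacies(self.n_ligands)
        if self.kd_grid is None:
            self.kd_grid = _default_kds(self.n_ligands)
        if len(self.efficacy_grid) != self.n_ligands or len(self.kd_grid) != self.n_ligands:
            raise ValueError("efficacy_grid and kd_grid must have n_ligands entries")
        if any(e <= 0 for e in self.efficacy_grid):
            raise ValueError("efficacies must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        ref = self.ligand_ids[0]
        if self.bias_map.get(ref, 1.0) != 1.0:
            raise ValueError("the reference ligand cannot carry an injected bias")

    @property
    def ligand_ids(self) -> Tuple[str, ...]:
        return ("REF", *(f"L{i:02d}" for i in range(1, self.n_ligands)))

    @property
    def reference_ligand(self) -> str:
        return self.ligand_ids[0]

    def kds(self) -> Dict[str, LigandKd]:
        return {
            lig: LigandKd(lig, float(np.log10(kd)))
            for lig, kd in zip(self.ligand_ids, self.kd_grid)
        }


def simulate_panels(cfg: SimConfig) -> Tuple[AssayPanel, AssayPanel, pd.DataFrame]:
    """Generate the two normalized assay panels and the ground-truth table.

    Returns ``(panel_a, panel_b, truth)`` where *truth* records, per ligand,
    the efficacy, K_d, injected bias multiplier and the expected log10 bias
    factor (panel A over panel B, reference-scaled): -log10(bias multiplier).
    Bit-reproducible given ``cfg.seed``.
    """
    if max(cfg.efficacy_grid) > cfg.efficacy_grid[0]:
        warnings.warn(
            "reference ligand is not the top-efficacy ligand; the reference "
            "trajectory assumes a full agonist", stacklevel=2,
        )
    rng = np.random.default_rng(cfg.seed)
    conc = np.asarray(cfg.conc_grid, dtype=float)
    panels = {}
    for assay_id, transfer, biased in (
        (cfg.assay_a, cfg.transfer_a, False),
        (cfg.assay_b, cfg.transfer_b, True),
    ):
        curves = {}
        for lig, eps, kd in zip(cfg.ligand_ids, cfg.efficacy_grid, cfg.kd_grid):
            mult = cfg.bias_map.get(lig, 1.0) if biased else 1.0
            occupancy = conc / (conc + kd)
            true = transfer(eps * mult * occupancy)
            if cfg.noise_sd > 0:
                reps = true + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_replicates, conc.size))
                resp = reps.mean(axis=0)
                sd = np.full(conc.size, cfg.noise_sd / np.sqrt(cfg.n_replicates))
            else:
                resp = true
                sd = np.zeros(conc.size)
            curves[lig] = CRCurve(lig, assay_id, conc, resp, sd, cfg.n_replicates)
        panels[assay_id] = normalize_panel(
            AssayPanel(assay_id, curves, cfg.reference_ligand)
        )
    truth = pd.DataFrame(
        {
            "ligand": cfg.ligand_ids,
            "efficacy": cfg.efficacy_grid,
            "kd_M": cfg.kd_grid,
            "bias_multiplier": [cfg.bias_map.get(l, 1.0) for l in cfg.ligand_ids],
        }
    )
    truth["is_biased"] = truth["bias_multiplier"] != 1.0
    truth["expected_bias_factor"] = -np.log10(truth["bias_multiplier"])
    return panels[cfg.assay_a], panels[cfg.assay_b], truth


def make_fixture_suite(seed: int, out_dir: str | Path) -> Dict[str, Path]:
    """Emit the canonical CSV fixture set under *out_dir*; returns the file map.

    Three panel pairs are written: ``unbiased`` (pure system bias), ``biased``
    (one ligand with a 10-fold efficacy drop injected in pathway B) and
    ``duplicate`` (the same transfer function observed twice with independent
    noise — the same-response negative control), plus the K_d table, the
    intrinsic-activity table of the unbiased pair, and a ground-truth manifest.
    Byte-identical across reruns with the same seed.
    """
    from .model_free import panel_intrinsic_activities

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: Dict[str, Path] = {}
    manifest = {"seed": int(seed), "pairs": {}}

    configs = {
        "unbiased": SimConfig(seed=seed),
        "biased": SimConfig(seed=seed + 1, bias_map={"L06": 0.1}),
        "duplicate": SimConfig(
            seed=seed + 2,
            transfer_b=TransferFunction(k_e=0.1),
            assay_a="dupA", assay_b="dupB",
        ),
    }
    for name, cfg in configs.items():
        pa, pb, truth = simulate_panels(cfg)
        fa, fb = out / f"{name}_A.csv", out / f"{name}_B.csv"
        write_panel_csv(pa, fa)
        write_panel_csv(pb, fb)
        files[f"{name}_A"], files[f"{name}_B"] = fa, fb
        manifest["pairs"][name] = {
            "assay_a": cfg.assay_a,
            "assay_b": cfg.assay_b,
            "reference_ligand": cfg.reference_ligand,
            "biased_ligands": {
                row.ligand: row.bias_multiplier
                for row in truth.itertuples() if row.is_biased
            },
            "expected_bias_factors": dict(zip(truth["ligand"],
                                              truth["expected_bias_factor"])),
        }
        if name == "unbiased":
            kd_path = out / "kd.csv"
            write_kd_csv(cfg.kds(), kd_path)
            files["kd"] = kd_path
            ias = {
                cfg.assay_a: panel_intrinsic_activities(pa),
                cfg.assay_b: panel_intrinsic_activities(pb),
            }
            ia_path = out / "ia.csv"
            write_ia_csv(ias, ia_path)
            files["ia"] = ia_path
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    files["manifest"] = manifest_path
    return files
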