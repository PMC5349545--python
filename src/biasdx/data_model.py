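"""Domain types and normalization rules shared by all bias-diagnostic methods.

The central objects are concentration-response (CR) curves — one ligand observed
in one assay — grouped into :class:`AssayPanel` objects keyed by ligand. All
responses are dimensionless and, after :func:`normalize_panel`, expressed as
fractions of the reference (full) agonist's fitted maximum in that assay, so
that intrinsic activities are directly comparable across assays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "CRCurve",
    "LigandKd",
    "AssayPanel",
    "IntrinsicActivity",
    "BiasResult",
    "NormalizationError",
    "normalize_panel",
    "read_panel_csv",
    "write_panel_csv",
    "read_kd_csv",
    "write_kd_csv",
    "read_ia_csv",
    "write_ia_csv",
]


class NormalizationError(RuntimeError):
    """Raised when the reference curve of a panel cannot be fitted."""


@dataclass(frozen=True)
class CRCurve:
    """A concentration-response curve: one ligand in one assay.

    Concentrations are molar; responses are mean values across replicate
    experiments (dimensionless, normalized), with per-point standard
    deviations of those means.
    """

    ligand_id: str
    assay_id: str
    conc: np.ndarray
    resp: np.ndarray
    resp_sd: np.ndarray
    n_replicates: int = 3

    def __post_init__(self) -> None:
        conc = np.asarray(self.conc, dtype=float)
        resp = np.asarray(self.resp, dtype=float)
        sd = np.asarray(self.resp_sd, dtype=float)
        if not (conc.shape == resp.shape == sd.shape) or conc.ndim != 1:
            raise ValueError(
                f"{self.ligand_id}/{self.assay_id}: conc, resp, resp_sd must be "
                "1-D vectors of equal length"
            )
        if conc.size < 4:
            raise ValueError(
                f"{self.ligand_id}/{self.assay_id}: need >=4 points to fit a "
                "3-parameter curve with at least 1 df"
            )
        if np.any(conc <= 0) or not np.all(np.isfinite(conc)):
            raise ValueError(f"{self.ligand_id}/{self.assay_id}: concentrations must be finite and > 0")
        if not np.all(np.isfinite(resp)):
            raise ValueError(f"{self.ligand_id}/{self.assay_id}: responses must be finite")
        if np.any(sd < 0) or not np.all(np.isfinite(sd)):
            raise ValueError(f"{self.ligand_id}/{self.assay_id}: resp_sd must be finite and >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be a positive integer")
        order = np.argsort(conc)
        conc, resp, sd = conc[order], resp[order], sd[order]
        if np.any(np.diff(conc) <= 0):
            raise ValueError(
                f"{self.ligand_id}/{self.assay_id}: duplicate concentrations are not allowed"
            )
        # frozen dataclass: bypass __setattr__ to store the sorted copies
        object.__setattr__(self, "conc", conc)
        object.__setattr__(self, "resp", resp)
        object.__setattr__(self, "resp_sd", sd)

    def scaled(self, factor: float) -> "CRCurve":
        """Return a copy with responses (and their SDs) multiplied by *factor*."""
        return replace(self, resp=self.resp * factor, resp_sd=self.resp_sd * factor)


@dataclass(frozen=True)
class LigandKd:
    """Equilibrium dissociation constant of a ligand, from binding assays
    performed in the absence of receptor-transducer interaction."""

    ligand_id: str
    log_kd: float  # log10 of K_d in molar

    def __post_init__(self) -> None:
        if not np.isfinite(self.log_kd):
            raise ValueError(f"{self.ligand_id}: log_kd must be finite")
        if not (-30.0 < self.log_kd < 0.0):
            warnings.warn(
                f"{self.ligand_id}: K_d = {self.kd:.3g} M is outside the plausible "
                "(0, 1) M range for a ligand",
                stacklevel=2,
            )

    @property
    def kd(self) -> float:
        return 10.0 ** self.log_kd


@dataclass
class AssayPanel:
    """All CR curves measured in one assay, with a designated reference agonist."""

    assay_id: str
    curves: Dict[str, CRCurve]
    reference_ligand: str

    def __post_init__(self) -> None:
        if self.reference_ligand not in self.curves:
            raise ValueError(
                f"reference ligand {self.reference_ligand!r} has no curve in assay "
                f"{self.assay_id!r}"
            )
        for lig, curve in self.curves.items():
            if curve.assay_id != self.assay_id:
                raise ValueError(
                    f"curve {lig!r} carries assay id {curve.assay_id!r}, expected "
                    f"{self.assay_id!r}"
                )
            if curve.ligand_id != lig:
                raise ValueError(f"curve keyed {lig!r} carries ligand id {curve.ligand_id!r}")

    @property
    def ligands(self) -> Tuple[str, ...]:
        return tuple(self.curves)

    @property
    def reference_curve(self) -> CRCurve:
        return self.curves[self.reference_ligand]


@dataclass(frozen=True)
class IntrinsicActivity:
    """Maximal response of a ligand as a fraction of the reference maximum."""

    ligand_id: str
    assay_id: str
    ia: float
    ia_sd: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.ia):
            raise ValueError(f"{self.ligand_id}/{self.assay_id}: ia must be finite")
        if self.ia_sd < 0 or not np.isfinite(self.ia_sd):
            raise ValueError(f"{self.ligand_id}/{self.assay_id}: ia_sd must be finite and >= 0")


@dataclass
class BiasResult:
    """Per-ligand outcome of one bias-diagnostic method on one assay pair.

    ``bias_factor`` is the log10 relative-efficacy ratio for methods 1-7 and
    ``None`` for the categorical methods 8-9. ``flagged`` is the biased /
    unbiased call against the method's 95% criterion.
    """

    ligand_id: str
    method_id: int
    assay_pair: Tuple[str, str]
    bias_factor: Optional[float]
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    flagged: bool = False
    warnings: Tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (1 <= self.method_id <= 9):
            raise ValueError("method_id must be in 1..9")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_panel(panel: AssayPanel) -> AssayPanel:
    """Rescale every curve of *panel* so the reference agonist's fitted maximum is 1.

    The reference curve is fitted with the 3-parameter logistic and every
    response (and its SD) in the panel is divided by the fitted E_max. The
    operation is idempotent and scale-equivariant: multiplying all raw
    responses by any k > 0 gives the same normalized panel.
    """
    from .curve_fitting import FitError, fit_logistic3

    try:
        ref_fit = fit_logistic3(panel.reference_curve)
    except FitError as exc:  # pragma: no cover - exercised via error test
        raise NormalizationError(
            f"assay {panel.assay_id!r}: reference ligand "
            f"{panel.reference_ligand!r} could not be fitted: {exc}"
        ) from exc
    factor = 1.0 / ref_fit.e_max
    curves = {lig: c.scaled(factor) for lig, c in panel.curves.items()}
    return AssayPanel(panel.assay_id, curves, panel.reference_ligand)


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------
# CR CSV columns: ligand,assay,conc_M,response,resp_sd ; K_d CSV: ligand,log10_Kd_M
# IA CSV: ligand,assay,ia,ia_sd. UTF-8, header required.

def read_panel_csv(path: str | Path, reference_ligand: str, assay_id: str | None = None,
                   n_replicates: int = 3) -> AssayPanel:
    """Load one assay's CR curves from CSV (columns ligand,assay,conc_M,response,resp_sd)."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"ligand", "assay", "conc_M", "response", "resp_sd"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    if assay_id is None:
        assays = df["assay"].unique()
        if len(assays) != 1:
            raise ValueError(f"{path}: multiple assays {list(assays)}; pass assay_id")
        assay_id = str(assays[0])
    sub = df[df["assay"] == assay_id]
    curves = {}
    for lig, grp in sub.groupby("ligand", sort=False):
        curves[str(lig)] = CRCurve(
            ligand_id=str(lig),
            assay_id=assay_id,
            conc=grp["conc_M"].to_numpy(float),
            resp=grp["response"].to_numpy(float),
            resp_sd=grp["resp_sd"].to_numpy(float),
            n_replicates=n_replicates,
        )
    return AssayPanel(assay_id, curves, reference_ligand)


def write_panel_csv(panel: AssayPanel, path: str | Path) -> None:
    rows = []
    for curve in panel.curves.values():
        for c, r, s in zip(curve.conc, curve.resp, curve.resp_sd):
            rows.append((curve.ligand_id, curve.assay_id, repr(float(c)), repr(float(r)), repr(float(s))))
    df = pd.DataFrame(rows, columns=["ligand", "assay", "conc_M", "response", "resp_sd"])
    df.to_csv(path, index=False)


def read_kd_csv(path: str | Path) -> Dict[str, LigandKd]:
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"ligand", "log10_Kd_M"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns ligand,log10_Kd_M")
    return {str(row.ligand): LigandKd(str(row.ligand), float(row.log10_Kd_M))
            for row in df.itertuples()}


def write_kd_csv(kds: Dict[str, LigandKd], path: str | Path) -> None:
    df = pd.DataFrame(
        [(k.ligand_id, repr(float(k.log_kd))) for k in kds.values()],
        columns=["ligand", "log10_Kd_M"],
    )
    df.to_csv(path, index=False)


def read_ia_csv(path: str | Path) -> Dict[str, Dict[str, IntrinsicActivity]]:
    """Load intrinsic activities; returns mapping assay -> ligand -> IA."""
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"ligand", "assay", "ia", "ia_sd"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns ligand,assay,ia,ia_sd")
    out: Dict[str, Dict[str, IntrinsicActivity]] = {}
    for row in df.itertuples():
        ia = IntrinsicActivity(str(row.ligand), str(row.assay), float(row.ia), float(row.ia_sd))
        out.setdefault(ia.assay_id, {})[ia.ligand_id] = ia
    return out


def write_ia_csv(ias: Dict[str, Dict[str, IntrinsicActivity]], path: str | Path) -> None:
    rows = [
        (ia.ligand_id, ia.assay_id, repr(float(ia.ia)), repr(float(ia.ia_sd)))
        for per_assay in ias.values()
        for ia in per_assay.values()
    ]
    pd.DataFrame(rows, columns=["ligand", "assay", "ia", "ia_sd"]).to_csv(path, index=False)
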