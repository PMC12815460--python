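"""Mass-action 1:1 binding equilibria under ligand depletion.

At the concentrations typical of weak protein-protein interactions
(tens to hundreds of micromolar), the free-ligand approximation of the
hyperbolic binding isotherm fails: a substantial share of the ligand is
consumed by the complex.  The exact solution of the 1:1 mass-action
system for the bound fraction of the observed protein P is the quadratic

    f = ([L] + [P] + K_D - sqrt(([L] + [P] + K_D)^2 - 4 [P][L])) / (2 [P])

with [P], [L] the *total* protein and ligand concentrations.  An NMR
titration observes a population-weighted response (fast exchange), so the
chemical-shift change of a reporter resonance is dd = dd_max * f, and K_D
and dd_max are obtained by nonlinear least squares.

The module also implements a minimal coupled-equilibrium model for
adaptor recruitment that requires prior activation of the observed
protein by a phosphopeptide: the apparent adaptor affinity is the
intrinsic affinity diluted by the activated fraction,
K_D,app = K_D,intrinsic / f_act.  This is a deliberate simplification
(activation and adaptor binding treated as independent equilibria).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import FitDegenerateError, InvalidParameterError, UndefinedAffinityError

__all__ = [
    "TitrationPoint",
    "TitrationSeries",
    "FitResult",
    "CoupledSystem",
    "fraction_bound",
    "predicted_response",
    "fit_kd",
    "solve_complex",
    "apparent_adaptor_kd",
]


@dataclass(frozen=True)
class TitrationPoint:
    """One titration point: total ligand (uM) and observed response (ppm)."""

    ligand_total: float
    response: float

    def __post_init__(self) -> None:
        if self.ligand_total < 0:
            raise InvalidParameterError(f"ligand_total must be >= 0, got {self.ligand_total}")
        if not math.isfinite(self.response):
            raise InvalidParameterError("response must be finite")


@dataclass(frozen=True)
class TitrationSeries:
    """An ordered titration of one reporter resonance.

    Parameters
    ----------
    protein_total:
        Total concentration of the observed (labelled) protein, uM.
        Held constant across the titration.
    points:
        Titration points with distinct total-ligand concentrations.
    label:
        Free-text identifier of the reporter (e.g. ``"I377 CD1"``).
    """

    protein_total: float
    points: tuple[TitrationPoint, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if self.protein_total <= 0:
            raise InvalidParameterError(f"protein_total must be > 0, got {self.protein_total}")
        object.__setattr__(self, "points", tuple(self.points))
        ligands = [p.ligand_total for p in self.points]
        if len(set(ligands)) != len(ligands):
            raise InvalidParameterError("ligand_total values must be distinct")

    @property
    def ligand_totals(self) -> np.ndarray:
        return np.array([p.ligand_total for p in self.points], dtype=float)

    @property
    def responses(self) -> np.ndarray:
        return np.array([p.response for p in self.points], dtype=float)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class FitResult:
    """Result of a 1:1 isotherm fit.

    ``kd`` / ``response_max`` are the point estimates (uM / ppm);
    standard errors come from the linearized covariance at the optimum.
    ``converged`` reflects the optimizer's own status and must be checked
    before trusting the estimates.
    """

    kd: float
    kd_stderr: float
    response_max: float
    response_max_stderr: float
    residuals: tuple[float, ...]
    converged: bool

    def to_dict(self) -> dict:
        return {
            "kd_uM": self.kd,
            "kd_stderr_uM": self.kd_stderr,
            "response_max_ppm": self.response_max,
            "response_max_stderr_ppm": self.response_max_stderr,
            "residuals_ppm": list(self.residuals),
            "converged": self.converged,
        }


@dataclass(frozen=True)
class CoupledSystem:
    """Activation->adaptor coupled equilibria.

    ``kd_activation`` is the phosphopeptide-protein dissociation constant,
    ``kd_intrinsic`` the adaptor affinity of the fully activated protein;
    ``arrestin_total`` and ``peptide_total`` set the activation equilibrium.
    All concentrations in uM.  ``peptide_total`` may be zero (no activation).
    """

    kd_activation: float
    kd_intrinsic: float
    arrestin_total: float
    peptide_total: float

    def __post_init__(self) -> None:
        for name in ("kd_activation", "kd_intrinsic", "arrestin_total"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.peptide_total < 0:
            raise InvalidParameterError("peptide_total must be >= 0")


def fraction_bound(protein_total, ligand_total, kd):
    """Bound fraction of the observed protein under ligand depletion.

    Exact quadratic solution of the 1:1 mass-action system in *total*
    concentrations.  Accepts scalar or array ``ligand_total``; the result
    lies in [0, min(1, L/P)].

    Parameters are in consistent concentration units (uM throughout this
    package).
    """
    if protein_total <= 0:
        raise InvalidParameterError(f"protein_total must be > 0, got {protein_total}")
    if kd <= 0:
        raise InvalidParameterError(f"kd must be > 0, got {kd}")
    ligand = np.asarray(ligand_total, dtype=float)
    if np.any(ligand < 0):
        raise InvalidParameterError("ligand_total must be >= 0")
    s = ligand + protein_total + kd
    # discriminant is mathematically >= (kd + |L - P|)^2 > 0; clip guards rounding
    disc = np.clip(s * s - 4.0 * protein_total * ligand, 0.0, None)
    frac = (s - np.sqrt(disc)) / (2.0 * protein_total)
    frac = np.clip(frac, 0.0, 1.0)
    if np.isscalar(ligand_total) or np.ndim(ligand_total) == 0:
        return float(frac)
    return frac


def predicted_response(protein_total, ligand_total, kd, response_max):
    """Population-weighted observed response: ``response_max * fraction_bound``."""
    if not np.all(np.isfinite(np.asarray(response_max, dtype=float))):
        raise InvalidParameterError("response_max must be finite")
    return response_max * fraction_bound(protein_total, ligand_total, kd)


def solve_complex(a_total: float, b_total: float, kd: float) -> float:
    """Equilibrium complex concentration for a 1:1 A+B binding pair.

    Forward companion of :func:`endoquant.sec_quant.apparent_kd`:
    feeding the returned concentration back recovers ``kd`` exactly.
    All arguments and the result in uM.
    """
    if a_total <= 0 or b_total <= 0:
        raise InvalidParameterError("totals must be > 0")
    return a_total * fraction_bound(a_total, b_total, kd)


def _default_init(series: TitrationSeries) -> tuple[float, float]:
    # robust scale-aware defaults: K_D at the median titrant concentration,
    # amplitude slightly above the largest observed response
    kd0 = float(np.median(series.ligand_totals))
    if kd0 <= 0:
        kd0 = float(np.max(series.ligand_totals)) / 2 or 1.0
    rmax0 = 1.2 * float(np.max(np.abs(series.responses)))
    if rmax0 == 0:
        rmax0 = 1.0
    return kd0, rmax0


def fit_kd(series: TitrationSeries, init: tuple[float, float] | None = None) -> FitResult:
    """Fit (K_D, dd_max) of the 1:1 depletion isotherm by least squares.

    Unweighted residuals; K_D constrained positive, dd_max free in sign.
    Standard errors are 1-sigma values from the Gauss-Newton covariance
    ``s^2 (J^T J)^{-1}`` at the optimum.

    Raises
    ------
    InvalidParameterError
        Fewer than 3 points.
    FitDegenerateError
        All responses identical (no curvature to fit).
    """
    if len(series) < 3:
        raise InvalidParameterError("need >= 3 titration points to fit")
    ligands = series.ligand_totals
    obs = series.responses
    if np.ptp(obs) == 0:
        raise FitDegenerateError("all responses identical; isotherm fit is degenerate")

    p0 = np.array(init if init is not None else _default_init(series), dtype=float)
    ptot = series.protein_total

    def resid(params: np.ndarray) -> np.ndarray:
        kd, rmax = params
        return predicted_response(ptot, ligands, kd, rmax) - obs

    sol = least_squares(
        resid,
        p0,
        bounds=([1e-12, -np.inf], [np.inf, np.inf]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    converged = bool(sol.status > 0 and np.all(np.isfinite(sol.x)))

    dof = max(len(series) - 2, 1)
    s2 = 2.0 * sol.cost / dof
    jtj = sol.jac.T @ sol.jac
    try:
        cov = s2 * np.linalg.inv(jtj)
        stderr = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        stderr = np.array([np.nan, np.nan])
        converged = False

    return FitResult(
        kd=float(sol.x[0]),
        kd_stderr=float(stderr[0]),
        response_max=float(sol.x[1]),
        response_max_stderr=float(stderr[1]),
        residuals=tuple(float(r) for r in sol.fun),
        converged=converged,
    )


def apparent_adaptor_kd(system: CoupledSystem) -> float:
    """Apparent adaptor affinity under partial activation.

    With activated fraction ``f_act`` set by the peptide-protein
    equilibrium, only ``f_act`` of the protein presents the adaptor-binding
    element, so the apparent dissociation constant is
    ``kd_intrinsic / f_act``.  Equals ``kd_intrinsic`` at peptide
    saturation and diverges as the peptide is withdrawn.
    """
    f_act = fraction_bound(system.arrestin_total, system.peptide_total, system.kd_activation)
    if f_act <= 0:
        raise UndefinedAffinityError("activated fraction is zero; apparent affinity undefined")
    return system.kd_intrinsic / f_act
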