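"""SEC-based complex quantification and mass-balance apparent K_D.

An analytical size-exclusion run of an A+B mixture that forms a 1:1
complex shows an extra peak at the complex elution volume.  The amount
of complex is obtained by integrating the A280 trace over the complex
window, subtracting the same integral of the apo reference (the
partner whose profile overlaps the window), and converting the excess
absorbance to concentration through Beer-Lambert with the extinction
coefficient of the species that newly entered the window:

    c = (I_mix - I_ref) / (epsilon * path * V_inj)

where I is in AU*ml, epsilon in M^-1 cm^-1, path in cm and V_inj in ml;
c refers to the injected sample.  With measured complex c and known
totals the apparent dissociation constant follows from mass balance:

    K_D,app = (A_tot - c)(B_tot - c) / c
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .errors import (
    InvalidParameterError,
    NoComplexError,
    SuperStoichiometricError,
    WindowOverlapError,
)

__all__ = [
    "Chromatogram",
    "QuantConfig",
    "ComplexQuantification",
    "integrate_window",
    "complex_concentration",
    "apparent_kd",
    "quantify_complex",
]

DEFAULT_WINDOW = (2.4, 2.8)  # ml, around the 2.6 ml complex elution volume


@dataclass(frozen=True)
class Chromatogram:
    """A280 elution trace: strictly increasing volumes (ml) vs absorbance (AU)."""

    volumes: np.ndarray
    absorbance: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.volumes, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if v.ndim != 1 or v.size < 2 or v.size != a.size:
            raise InvalidParameterError("need >= 2 (volume, absorbance) pairs of equal length")
        if not np.all(np.diff(v) > 0):
            raise InvalidParameterError("volumes must be strictly increasing")
        if not np.all(np.isfinite(a)):
            raise InvalidParameterError("absorbance must be finite")
        object.__setattr__(self, "volumes", v)
        object.__setattr__(self, "absorbance", a)


@dataclass(frozen=True)
class QuantConfig:
    """Optics and geometry for absorbance-to-concentration conversion.

    ``epsilon`` (M^-1 cm^-1) is the extinction coefficient of the species
    whose absorbance is newly added to the window (the partner joining the
    complex); ``path_cm`` the detector path length; ``injection_volume_ml``
    the injected sample volume (250 uL loop by default); ``window`` the
    complex integration window in ml.
    """

    epsilon: float
    path_cm: float = 1.0
    injection_volume_ml: float = 0.25
    window: tuple[float, float] = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        if self.epsilon <= 0 or self.path_cm <= 0 or self.injection_volume_ml <= 0:
            raise InvalidParameterError("epsilon, path_cm, injection_volume_ml must be > 0")
        lo, hi = self.window
        if not lo < hi:
            raise InvalidParameterError("window must satisfy v_lo < v_hi")


@dataclass(frozen=True)
class ComplexQuantification:
    """Complex concentration (uM, injected sample), apparent K_D and raw integrals."""

    complex_conc: float
    kd_app: float
    integrals: tuple[float, float]  # (mixture, apo reference), AU*ml

    def to_dict(self) -> dict:
        return {
            "complex_conc_uM": self.complex_conc,
            "kd_app_uM": self.kd_app,
            "integral_mixture_AU_ml": self.integrals[0],
            "integral_apo_AU_ml": self.integrals[1],
        }


def integrate_window(chrom: Chromatogram, window: tuple[float, float]) -> float:
    """Trapezoidal integral of the trace over ``window`` (AU*ml).

    The window edges are linearly interpolated onto the trace; a window
    entirely outside the recorded volume range raises
    :class:`WindowOverlapError`.
    """
    lo, hi = window
    if not lo < hi:
        raise InvalidParameterError("window must satisfy v_lo < v_hi")
    v, a = chrom.volumes, chrom.absorbance
    if hi <= v[0] or lo >= v[-1]:
        raise WindowOverlapError(
            f"window [{lo}, {hi}] ml does not overlap trace range [{v[0]}, {v[-1]}] ml"
        )
    lo_c, hi_c = max(lo, float(v[0])), min(hi, float(v[-1]))
    inside = (v > lo_c) & (v < hi_c)
    grid = np.concatenate(([lo_c], v[inside], [hi_c]))
    vals = np.interp(grid, v, a)
    return float(np.trapezoid(vals, grid))


def complex_concentration(
    mixture: Chromatogram, apo_reference: Chromatogram, config: QuantConfig
) -> float:
    """Complex concentration in the injected sample (uM).

    Integrates both traces over the configured window, subtracts the apo
    reference and converts the excess through Beer-Lambert.  A negative
    excess is clamped to zero with a warning (no complex detectable).
    Peptide absorbance is ignored (no tryptophan).
    """
    i_mix = integrate_window(mixture, config.window)
    i_apo = integrate_window(apo_reference, config.window)
    diff = i_mix - i_apo
    if diff < 0:
        warnings.warn(
            "mixture window integral below apo reference; clamping complex to 0",
            stacklevel=2,
        )
        diff = 0.0
    # AU*ml / (M^-1 cm^-1 * cm) = M*ml; / ml -> M; *1e6 -> uM
    return 1e6 * diff / (config.epsilon * config.path_cm * config.injection_volume_ml)


def apparent_kd(complex_conc: float, a_total: float, b_total: float) -> float:
    """Mass-balance apparent K_D from measured complex and total concentrations."""
    if a_total <= 0 or b_total <= 0:
        raise InvalidParameterError("totals must be > 0")
    if complex_conc <= 0:
        raise NoComplexError("complex concentration <= 0; K_D undefined")
    if complex_conc >= min(a_total, b_total):
        raise SuperStoichiometricError(
            f"complex {complex_conc} uM >= min total {min(a_total, b_total)} uM"
        )
    return (a_total - complex_conc) * (b_total - complex_conc) / complex_conc


def quantify_complex(
    mixture: Chromatogram,
    apo_reference: Chromatogram,
    config: QuantConfig,
    a_total: float,
    b_total: float,
) -> ComplexQuantification:
    """Full chain: integrate, subtract, convert, and apply mass balance."""
    i_mix = integrate_window(mixture, config.window)
    i_apo = integrate_window(apo_reference, config.window)
    conc = complex_concentration(mixture, apo_reference, config)
    kd = apparent_kd(conc, a_total, b_total)
    return ComplexQuantification(complex_conc=conc, kd_app=kd, integrals=(i_mix, i_apo))
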