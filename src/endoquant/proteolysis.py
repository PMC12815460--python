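"""Limited-proteolysis gel densitometry.

A limited trypsin digest cleaves the substrate at a single exposed site,
splitting each gel lane into a full-length (top) and a cleaved (bottom)
band.  The relative abundance of full-length protein,
100 * top / (top + bottom), is followed over time; the digestion
midpoint is the time at which it crosses 50%, linearly interpolated
between the bracketing samples.  Conditions that slow the digest
(e.g. a bound partner burying the cleavage site) are compared through
the ratio of midpoints, the protection factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError, UndefinedAbundanceError

__all__ = [
    "BandMeasurement",
    "DigestionTimeCourse",
    "Midpoint",
    "ProtectionFactor",
    "relative_abundance",
    "digestion_midpoint",
    "protection_factor",
]


@dataclass(frozen=True)
class BandMeasurement:
    """Densitometry of one lane: time (min) and the two band integrals (AU)."""

    time: float
    full_length: float
    cleaved: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise InvalidParameterError("time must be >= 0")
        if self.full_length < 0 or self.cleaved < 0:
            raise InvalidParameterError("band densities must be >= 0")


@dataclass(frozen=True)
class DigestionTimeCourse:
    """Strictly increasing time course for one condition, starting at t = 0."""

    condition_label: str
    measurements: tuple[BandMeasurement, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "measurements", tuple(self.measurements))
        if len(self.measurements) < 2:
            raise InvalidParameterError("need >= 2 time points")
        times = [m.time for m in self.measurements]
        if times[0] != 0:
            raise InvalidParameterError("first time point must be 0")
        if not all(b > a for a, b in zip(times, times[1:])):
            raise InvalidParameterError("times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([m.time for m in self.measurements])

    def abundances(self) -> np.ndarray:
        return np.array([relative_abundance(m) for m in self.measurements])


@dataclass(frozen=True)
class Midpoint:
    """Digestion midpoint in minutes; ``censored`` when 50% was never reached."""

    time_min: float
    censored: bool = False


@dataclass(frozen=True)
class ProtectionFactor:
    """midpoint(protected) / midpoint(reference); ``lower_bound`` if censored."""

    value: float
    lower_bound: bool = False


def relative_abundance(m: BandMeasurement) -> float:
    """Percent full-length protein in one lane: 100 * top / (top + bottom)."""
    total = m.full_length + m.cleaved
    if total <= 0:
        raise UndefinedAbundanceError(f"both bands zero at t = {m.time} min")
    return 100.0 * m.full_length / total


def digestion_midpoint(tc: DigestionTimeCourse) -> Midpoint:
    """First 50%-crossing time of the relative-abundance curve.

    Linear interpolation between the bracketing samples.  If the curve
    never drops to 50% the result is right-censored at the last time; if
    it starts at or below 50% the sample is flagged pre-digested and the
    midpoint is 0 (with a warning).
    """
    times = tc.times
    ab = tc.abundances()
    if ab[0] <= 50.0:
        warnings.warn(
            f"{tc.condition_label or 'time course'}: abundance already <= 50% at t = 0 "
            "(pre-digested)",
            stacklevel=2,
        )
        return Midpoint(0.0, censored=False)
    below = np.nonzero(ab <= 50.0)[0]
    if below.size == 0:
        return Midpoint(float(times[-1]), censored=True)
    i = int(below[0])
    t0, t1 = times[i - 1], times[i]
    a0, a1 = ab[i - 1], ab[i]
    t_mid = t0 + (a0 - 50.0) / (a0 - a1) * (t1 - t0)
    return Midpoint(float(t_mid), censored=False)


def protection_factor(
    reference: DigestionTimeCourse, protected: DigestionTimeCourse
) -> ProtectionFactor:
    """Midpoint ratio protected/reference.

    A censored protected course gives a flagged lower bound
    (last observed time over the reference midpoint).  A censored
    reference midpoint leaves the ratio undefined.
    """
    ref_mid = digestion_midpoint(reference)
    prot_mid = digestion_midpoint(protected)
    if ref_mid.censored:
        raise InvalidParameterError("reference midpoint is right-censored; ratio undefined")
    if ref_mid.time_min <= 0:
        raise InvalidParameterError("reference midpoint is 0 (pre-digested); ratio undefined")
    return ProtectionFactor(
        value=prot_mid.time_min / ref_mid.time_min,
        lower_bound=prot_mid.censored,
    )
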