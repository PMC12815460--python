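"""Per-residue comparison of apo vs complexed NMR peak lists.

Binding of an unlabelled partner in intermediate exchange broadens the
resonances of interface residues, lowering the complexed/apo intensity
ratio I/I0; in fast exchange it shifts them, producing chemical shift
perturbations (CSPs).  Both observables are mapped per residue and
thresholded with a one-standard-deviation rule computed over all shared
resonances:

* attenuation: significant when I/I0 < mean - 1 SD (strictly below);
* CSP:         significant when dd_HC > mean + 1 SD (strictly above),

with the combined 1H/13C perturbation

    dd_HC = sqrt(dd_H^2 + (dd_X / 3.6)^2)

The 3.6 weight scales the carbon (or nitrogen) shift range onto the
proton range for methyl groups.  Sample (n-1) standard deviations are
used throughout; with zero variance nothing is significant.

Contiguous significant residues are merged into binding regions for
reporting (e.g. "374-381").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import EmptyOverlapError, InvalidParameterError
from .equilibrium import TitrationPoint, TitrationSeries

__all__ = [
    "AtomGroup",
    "Resonance",
    "PeakList",
    "AttenuationProfile",
    "CSPProfile",
    "BindingRegion",
    "intensity_ratios",
    "combined_csp",
    "segment_regions",
    "extract_titration",
]

X_WEIGHT_DEFAULT = 3.6


class AtomGroup(str, Enum):
    """Resonance class: backbone 1H-15N amide or Ile-d1 1H-13C methyl."""

    backbone_amide = "backbone_amide"
    ile_d1_methyl = "ile_d1_methyl"


@dataclass(frozen=True)
class Resonance:
    """One assigned resonance: shifts (ppm) and integrated intensity.

    ``shift_x`` is the 15N shift for backbone amides and the 13C shift
    for Ile-d1 methyls.  Shifts may be NaN to mark a missing value.
    """

    residue_number: int
    residue_type: str
    atom_group: AtomGroup
    shift_h: float
    shift_x: float
    intensity: float

    def __post_init__(self) -> None:
        if self.residue_number < 1:
            raise InvalidParameterError("residue_number must be >= 1")
        if self.intensity < 0:
            raise InvalidParameterError("intensity must be >= 0")

    @property
    def key(self) -> tuple[int, AtomGroup]:
        return (self.residue_number, self.atom_group)


@dataclass(frozen=True)
class PeakList:
    """Peak list for one sample condition, keyed by (residue, atom group)."""

    condition_label: str
    resonances: tuple[Resonance, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "resonances", tuple(self.resonances))
        if not self.resonances:
            raise InvalidParameterError("peak list must be nonempty")
        keys = [r.key for r in self.resonances]
        if len(set(keys)) != len(keys):
            raise InvalidParameterError("duplicate (residue_number, atom_group) keys")

    def by_key(self) -> dict[tuple[int, AtomGroup], Resonance]:
        return {r.key: r for r in self.resonances}


@dataclass(frozen=True)
class AttenuationProfile:
    """Per-residue I/I0 with the mean - 1 SD significance rule applied."""

    entries: dict[int, float]
    mean: float
    sd: float
    threshold: float
    significant: frozenset[int]
    excluded: tuple[tuple[int, str], ...] = ()


@dataclass(frozen=True)
class CSPProfile:
    """Per-residue combined CSP with the mean + 1 SD significance rule applied."""

    entries: dict[int, float]
    mean: float
    sd: float
    threshold: float
    significant: frozenset[int]
    excluded: tuple[tuple[int, str], ...] = ()


@dataclass(frozen=True, order=True)
class BindingRegion:
    """Inclusive residue interval of contiguous significant residues."""

    start_residue: int
    end_residue: int

    def __post_init__(self) -> None:
        if self.start_residue > self.end_residue:
            raise InvalidParameterError("start_residue must be <= end_residue")

    def __str__(self) -> str:  # the field's "374-381" reporting convention
        if self.start_residue == self.end_residue:
            return str(self.start_residue)
        return f"{self.start_residue}-{self.end_residue}"


def _sample_sd(values: np.ndarray) -> float:
    if len(values) < 2:
        return 0.0
    return float(np.std(values, ddof=1))


def intensity_ratios(apo: PeakList, bound: PeakList) -> AttenuationProfile:
    """Complexed/apo intensity ratios with one-SD attenuation significance.

    Only keys present in both lists enter the profile and the statistics;
    keys with zero apo intensity are excluded per-residue (reported in
    ``excluded``), never a global failure.
    """
    apo_map, bound_map = apo.by_key(), bound.by_key()
    shared = sorted(set(apo_map) & set(bound_map))
    if not shared:
        raise EmptyOverlapError("peak lists share no (residue, atom_group) keys")
    entries: dict[int, float] = {}
    excluded: list[tuple[int, str]] = []
    for key in shared:
        i0 = apo_map[key].intensity
        if i0 <= 0:
            excluded.append((key[0], "zero apo intensity"))
            continue
        entries[key[0]] = bound_map[key].intensity / i0
    if not entries:
        raise EmptyOverlapError("no usable shared resonances (all apo intensities zero)")
    vals = np.array(list(entries.values()))
    mean = float(np.mean(vals))
    sd = _sample_sd(vals)
    threshold = mean - sd
    significant = frozenset(r for r, v in entries.items() if v < threshold)
    return AttenuationProfile(entries, mean, sd, threshold, significant, tuple(excluded))


def combined_csp(
    apo: PeakList, bound: PeakList, x_weight: float = X_WEIGHT_DEFAULT
) -> CSPProfile:
    """Combined 1H/13C (or 1H/15N) CSPs with one-SD significance.

    dd_HC = sqrt(dd_H^2 + (dd_X / x_weight)^2), with dd = apo - bound.
    Keys missing a finite shift in either list are excluded and reported.
    """
    if x_weight <= 0:
        raise InvalidParameterError("x_weight must be > 0")
    apo_map, bound_map = apo.by_key(), bound.by_key()
    shared = sorted(set(apo_map) & set(bound_map))
    if not shared:
        raise EmptyOverlapError("peak lists share no (residue, atom_group) keys")
    entries: dict[int, float] = {}
    excluded: list[tuple[int, str]] = []
    for key in shared:
        a, b = apo_map[key], bound_map[key]
        shifts = (a.shift_h, a.shift_x, b.shift_h, b.shift_x)
        if not all(math.isfinite(s) for s in shifts):
            excluded.append((key[0], "missing shift"))
            continue
        dh = a.shift_h - b.shift_h
        dx = a.shift_x - b.shift_x
        entries[key[0]] = math.sqrt(dh * dh + (dx / x_weight) ** 2)
    if not entries:
        raise EmptyOverlapError("no shared resonances with finite shifts")
    vals = np.array(list(entries.values()))
    mean = float(np.mean(vals))
    sd = _sample_sd(vals)
    threshold = mean + sd
    significant = frozenset(r for r, v in entries.items() if v > threshold)
    return CSPProfile(entries, mean, sd, threshold, significant, tuple(excluded))


def segment_regions(significant: Iterable[int], max_gap: int = 0) -> list[BindingRegion]:
    """Merge significant residues into maximal contiguous regions.

    Successive residues are joined while the numbering gap is at most
    ``max_gap + 1`` (``max_gap=0`` joins only direct neighbours).
    """
    if max_gap < 0:
        raise InvalidParameterError("max_gap must be >= 0")
    residues = sorted(set(int(r) for r in significant))
    if not residues:
        return []
    regions: list[BindingRegion] = []
    start = prev = residues[0]
    for r in residues[1:]:
        if r - prev <= max_gap + 1:
            prev = r
        else:
            regions.append(BindingRegion(start, prev))
            start = prev = r
    regions.append(BindingRegion(start, prev))
    return regions


def extract_titration(
    series_of_peaklists: Sequence[tuple[float, PeakList]],
    key: tuple[int, AtomGroup],
    protein_total: float,
    metric: str = "x",
    x_weight: float = X_WEIGHT_DEFAULT,
) -> TitrationSeries:
    """Pull one resonance's shift response out of a titration of peak lists.

    ``metric="x"`` uses |delta shift| of the X dimension (13C for methyls,
    the convention for Ile-d1 titrations); ``metric="combined"`` uses the
    weighted 1H/X combination.  Responses are referenced to the
    zero-ligand list; ligand points where the key is missing are dropped.
    """
    if metric not in ("x", "combined"):
        raise InvalidParameterError(f"unknown metric {metric!r}")
    ordered = sorted(series_of_peaklists, key=lambda lp: lp[0])
    if not ordered or ordered[0][0] != 0:
        raise InvalidParameterError("titration must include a zero-ligand peak list")
    ref = ordered[0][1].by_key().get(key)
    if ref is None:
        raise InvalidParameterError(f"key {key} absent from the zero-ligand list")
    points = []
    residue, group = key
    label = f"{ref.residue_type}{residue} {group.value}"
    for ligand, plist in ordered:
        res = plist.by_key().get(key)
        if res is None:
            continue  # dropped point; downstream fit preconditions still apply
        if metric == "x":
            resp = abs(ref.shift_x - res.shift_x)
        else:
            dh = ref.shift_h - res.shift_h
            dx = ref.shift_x - res.shift_x
            resp = math.sqrt(dh * dh + (dx / x_weight) ** 2)
        points.append(TitrationPoint(ligand_total=ligand, response=resp))
    return TitrationSeries(protein_total=protein_total, points=tuple(points), label=label)
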