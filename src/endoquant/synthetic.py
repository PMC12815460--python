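"""Seeded synthetic-data generators with ground truth.

Each generator emulates the statistical structure of one experimental
input — saturable NMR titrations with ligand depletion, peak-list pairs
with a planted contiguous binding site, multi-species Gaussian SEC
traces obeying Beer-Lambert mass balance, first-order limited-proteolysis
decays, and two-channel puncta images with a set colocalization
fraction — and returns a machine-readable truth record alongside, so
every pipeline stage can be scored without external data.

All generators are pure functions of their arguments including the
seed (one ``numpy.random.default_rng`` per call, no global state).
Noise is additive Gaussian except for gel band densities, where it is
multiplicative (densitometry errors scale with band size).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .coloc_imaging import ChannelImage, TwoChannelImage
from .equilibrium import (
    TitrationPoint,
    TitrationSeries,
    fraction_bound,
    predicted_response,
    solve_complex,
)
from .errors import InvalidParameterError
from .nmr_mapping import AtomGroup, BindingRegion, PeakList, Resonance
from .proteolysis import BandMeasurement, DigestionTimeCourse
from .sec_quant import Chromatogram, QuantConfig, integrate_window

__all__ = [
    "gen_titration",
    "gen_peaklist_pair",
    "gen_chromatogram_set",
    "gen_proteolysis",
    "gen_coloc_images",
]

# nominal A280 extinction coefficients (M^-1 cm^-1) for the two protein
# species of the SEC assay; plausible values for ~40 kDa and ~27 kDa
# constructs, configurable per call
EPSILON_A_DEFAULT = 30_000.0
EPSILON_B_DEFAULT = 20_000.0


def gen_titration(
    kd: float,
    response_max: float,
    protein_total: float,
    ligand_grid: Sequence[float],
    noise_sd: float,
    seed: int,
    label: str = "synthetic",
) -> tuple[TitrationSeries, dict]:
    """Saturable titration on the 1:1 depletion isotherm + Gaussian shift noise.

    Truth carries the planted (kd, response_max).
    """
    rng = np.random.default_rng(seed)
    ligands = np.asarray(ligand_grid, dtype=float)
    clean = predicted_response(protein_total, ligands, kd, response_max)
    noisy = clean + rng.normal(0.0, noise_sd, size=ligands.shape)
    points = tuple(
        TitrationPoint(ligand_total=float(l), response=float(r))
        for l, r in zip(ligands, noisy)
    )
    series = TitrationSeries(protein_total=protein_total, points=points, label=label)
    truth = {"kd_uM": kd, "response_max_ppm": response_max, "protein_total_uM": protein_total}
    return series, truth


def gen_peaklist_pair(
    n_residues: int,
    site: BindingRegion,
    attenuation_depth: float,
    csp_peak: float,
    noise_sd: float,
    seed: int,
    atom_group: AtomGroup = AtomGroup.backbone_amide,
    base_intensity: float = 100.0,
) -> tuple[PeakList, PeakList, dict]:
    """Apo/bound peak-list pair with a planted contiguous binding site.

    Inside the site, bound intensities are attenuated by
    ``attenuation_depth`` (fraction of signal lost) and the proton shift
    is perturbed by ``csp_peak`` ppm; outside, intensities and shifts are
    unchanged.  ``noise_sd`` is the Gaussian SD of the I/I0 ratio noise
    (applied to bound intensities) and, scaled by ``csp_peak``, of the
    shift noise.  Truth is the planted site.
    """
    if not (1 <= site.start_residue and site.end_residue <= n_residues):
        raise InvalidParameterError("site must lie within 1..n_residues")
    if not 0 <= attenuation_depth <= 1:
        raise InvalidParameterError("attenuation_depth must be in [0, 1]")
    rng = np.random.default_rng(seed)
    shift_h0 = rng.uniform(7.0, 9.5, n_residues)
    shift_x0 = rng.uniform(105.0, 130.0, n_residues)
    apo_int = base_intensity * rng.uniform(0.8, 1.2, n_residues)
    in_site = np.zeros(n_residues, dtype=bool)
    in_site[site.start_residue - 1 : site.end_residue] = True

    ratio = np.where(in_site, 1.0 - attenuation_depth, 1.0)
    ratio = ratio + rng.normal(0.0, noise_sd, n_residues)
    bound_int = np.clip(apo_int * ratio, 0.0, None)
    dh = np.where(in_site, csp_peak, 0.0) + rng.normal(0.0, noise_sd * csp_peak, n_residues)

    types = rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), n_residues)
    apo_res, bound_res = [], []
    for i in range(n_residues):
        common = dict(residue_number=i + 1, residue_type=str(types[i]), atom_group=atom_group)
        apo_res.append(
            Resonance(shift_h=float(shift_h0[i]), shift_x=float(shift_x0[i]),
                      intensity=float(apo_int[i]), **common)
        )
        bound_res.append(
            Resonance(shift_h=float(shift_h0[i] - dh[i]), shift_x=float(shift_x0[i]),
                      intensity=float(bound_int[i]), **common)
        )
    apo = PeakList(condition_label="apo", resonances=tuple(apo_res))
    bound = PeakList(condition_label="bound", resonances=tuple(bound_res))
    truth = {
        "site_start": site.start_residue,
        "site_end": site.end_residue,
        "attenuation_depth": attenuation_depth,
        "csp_peak_ppm": csp_peak,
    }
    return apo, bound, truth


def _gaussian_trace(volumes: np.ndarray, centre: float, sigma: float, area: float) -> np.ndarray:
    amp = area / (sigma * np.sqrt(2.0 * np.pi))
    return amp * np.exp(-0.5 * ((volumes - centre) / sigma) ** 2)


def gen_chromatogram_set(
    a_total: float = 10.0,
    b_total: float = 10.0,
    peptide_total: float = 100.0,
    kd_activation: float = 45.0,
    kd_intrinsic: float = 9.0,
    peak_centres: dict | None = None,
    peak_sigma: float = 0.04,
    epsilon_a: float = EPSILON_A_DEFAULT,
    epsilon_b: float = EPSILON_B_DEFAULT,
    config: QuantConfig | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[Chromatogram, dict[str, Chromatogram], dict]:
    """Mixture + apo-reference SEC traces under the coupled equilibrium.

    Species concentrations follow the activation-coupled 1:1 model:
    the peptide activates a fraction ``f_act`` of A, the apparent A-B
    affinity is ``kd_intrinsic / f_act``, and the complex concentration
    solves the mass-action quadratic at the given totals.  Each species
    elutes as a Gaussian whose area is its Beer-Lambert integral
    ``epsilon * path * c * V_inj`` (complex: sum of both epsilons), so
    window integration of a well-separated peak returns that integral.

    Default geometry places the complex at 2.6 ml and free A at 2.7 ml
    (both inside the 2.4-2.8 ml window) and free B at 3.1 ml (outside),
    matching the apo-subtraction quantification convention.  Truth
    records the planted complex concentration, apparent K_D and whether
    each species falls cleanly inside/outside the window.
    """
    rng = np.random.default_rng(seed)
    centres = {"complex": 2.6, "a": 2.7, "b": 3.1}
    if peak_centres:
        centres.update(peak_centres)
    cfg = config or QuantConfig(epsilon=epsilon_b)

    if peptide_total > 0:
        f_act = fraction_bound(a_total, peptide_total, kd_activation)
    else:
        f_act = 0.0
    if f_act > 0:
        kd_app = kd_intrinsic / f_act
        complex_conc = solve_complex(a_total, b_total, kd_app)
    else:
        kd_app = float("inf")
        complex_conc = 0.0
    free_a = a_total - complex_conc
    free_b = b_total - complex_conc

    volumes = np.arange(0.0, 4.2001, 0.002)
    scale = cfg.path_cm * cfg.injection_volume_ml * 1e-6  # uM -> AU*ml per epsilon

    def species(centre: float, conc: float, eps: float) -> np.ndarray:
        return _gaussian_trace(volumes, centre, peak_sigma, eps * conc * scale)

    mix = (
        species(centres["complex"], complex_conc, epsilon_a + epsilon_b)
        + species(centres["a"], free_a, epsilon_a)
        + species(centres["b"], free_b, epsilon_b)
    )
    apo_a = species(centres["a"], a_total, epsilon_a)
    apo_b = species(centres["b"], b_total, epsilon_b)
    if noise_sd > 0:
        mix = np.clip(mix + rng.normal(0.0, noise_sd, volumes.shape), 0.0, None)
        apo_a = np.clip(apo_a + rng.normal(0.0, noise_sd, volumes.shape), 0.0, None)
        apo_b = np.clip(apo_b + rng.normal(0.0, noise_sd, volumes.shape), 0.0, None)

    mixture = Chromatogram(volumes=volumes, absorbance=mix, label="mixture")
    references = {
        "apo_a": Chromatogram(volumes=volumes, absorbance=apo_a, label="apo_a"),
        "apo_b": Chromatogram(volumes=volumes, absorbance=apo_b, label="apo_b"),
    }

    lo, hi = cfg.window
    margin = 4.0 * peak_sigma

    def placement(centre: float) -> str:
        if lo + margin <= centre <= hi - margin:
            return "inside"
        if centre <= lo - margin or centre >= hi + margin:
            return "outside"
        return "straddles"

    truth = {
        "complex_conc_uM": complex_conc,
        "kd_app_uM": kd_app,
        "f_act": f_act,
        "free_a_uM": free_a,
        "free_b_uM": free_b,
        "window_placement": {name: placement(centres[name]) for name in centres},
    }
    return mixture, references, truth


def gen_proteolysis(
    k_obs: dict[str, float],
    times: Sequence[float] = (0, 5, 10, 20, 30, 60, 90),
    noise_sd: float = 0.0,
    seed: int = 0,
    total_density: float = 1000.0,
) -> tuple[dict[str, DigestionTimeCourse], dict]:
    """First-order digestion time courses, one per condition.

    Full-length band decays as exp(-k t); the cleaved band is the
    complement (two-band mass conservation).  ``noise_sd`` is the
    relative SD of multiplicative Gaussian densitometry noise.  Truth
    carries the half-lives ln2/k (inf for k = 0).
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(times, dtype=float)
    courses: dict[str, DigestionTimeCourse] = {}
    truth_half: dict[str, float] = {}
    for condition, k in k_obs.items():
        if k < 0:
            raise InvalidParameterError("k_obs must be >= 0")
        full_frac = np.exp(-k * t)
        full = total_density * full_frac
        cleaved = total_density * (1.0 - full_frac)
        if noise_sd > 0:
            full = full * np.clip(1.0 + rng.normal(0.0, noise_sd, t.shape), 0.0, None)
            cleaved = cleaved * np.clip(1.0 + rng.normal(0.0, noise_sd, t.shape), 0.0, None)
        measurements = tuple(
            BandMeasurement(time=float(ti), full_length=float(f), cleaved=float(c))
            for ti, f, c in zip(t, full, cleaved)
        )
        courses[condition] = DigestionTimeCourse(
            condition_label=condition, measurements=measurements
        )
        truth_half[condition] = float(np.log(2) / k) if k > 0 else float("inf")
    return courses, {"half_life_min": truth_half}


def _add_spot(img: np.ndarray, centre: tuple[float, float], sigma_px: float, amp: float) -> None:
    r0, c0 = centre
    half = int(np.ceil(4 * sigma_px))
    r_lo, r_hi = max(0, int(r0) - half), min(img.shape[0], int(r0) + half + 1)
    c_lo, c_hi = max(0, int(c0) - half), min(img.shape[1], int(c0) + half + 1)
    rows = np.arange(r_lo, r_hi)[:, None]
    cols = np.arange(c_lo, c_hi)[None, :]
    img[r_lo:r_hi, c_lo:c_hi] += amp * np.exp(
        -((rows - r0) ** 2 + (cols - c0) ** 2) / (2 * sigma_px**2)
    )


def _sample_centres(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    margin: float,
    min_dist: float,
    avoid: list[tuple[float, float]],
) -> list[tuple[float, float]]:
    centres: list[tuple[float, float]] = []
    attempts = 0
    while len(centres) < n and attempts < 20000:
        attempts += 1
        r = rng.uniform(margin, shape[0] - margin)
        c = rng.uniform(margin, shape[1] - margin)
        ok = all(
            (r - pr) ** 2 + (c - pc) ** 2 >= min_dist**2 for pr, pc in centres + avoid
        )
        if ok:
            centres.append((r, c))
    if len(centres) < n:
        raise InvalidParameterError("could not place puncta without overlap; lower n_puncta")
    return centres


def gen_coloc_images(
    n_puncta: int,
    coloc_fraction: float,
    image_size: int = 192,
    pixel_size: float = 0.1,
    psf_sigma: float = 0.2,
    snr: float = 10.0,
    seed: int = 0,
    amplitude: float = 1.0,
) -> tuple[TwoChannelImage, dict]:
    """Two-channel puncta image with a set colocalization fraction.

    The receptor channel carries ``n_puncta`` Gaussian spots (PSF sigma in
    um); the arrestin channel reproduces a ``coloc_fraction`` subset at
    identical positions plus independent spots elsewhere, so both channels
    hold the same number of puncta.  Gaussian background noise has
    SD = amplitude / snr.  Truth labels each receptor punctum as
    colocalized or not.
    """
    if not 0 <= coloc_fraction <= 1:
        raise InvalidParameterError("coloc_fraction must be in [0, 1]")
    if snr <= 0:
        raise InvalidParameterError("snr must be > 0")
    rng = np.random.default_rng(seed)
    shape = (image_size, image_size)
    sigma_px = psf_sigma / pixel_size
    margin = 5 * sigma_px
    min_dist = 8 * sigma_px  # keeps puncta resolvable and avoids chance coloc

    rec_centres = _sample_centres(rng, n_puncta, shape, margin, min_dist, [])
    n_coloc = int(round(coloc_fraction * n_puncta))
    coloc_centres = rec_centres[:n_coloc]
    n_indep = n_puncta - n_coloc
    indep_centres = _sample_centres(rng, n_indep, shape, margin, min_dist, rec_centres)

    rec = np.zeros(shape)
    arr = np.zeros(shape)
    for c in rec_centres:
        _add_spot(rec, c, sigma_px, amplitude)
    for c in coloc_centres + indep_centres:
        _add_spot(arr, c, sigma_px, amplitude)

    noise_sd = amplitude / snr
    rec = np.clip(rec + rng.normal(0.0, noise_sd, shape), 0.0, None)
    arr = np.clip(arr + rng.normal(0.0, noise_sd, shape), 0.0, None)

    img = TwoChannelImage(
        receptor=ChannelImage(pixels=rec, pixel_size=pixel_size),
        arrestin=ChannelImage(pixels=arr, pixel_size=pixel_size),
    )
    truth = {
        "n_puncta": n_puncta,
        "coloc_fraction": coloc_fraction,
        "receptor_centres": [list(c) for c in rec_centres],
        "colocalized": [i < n_coloc for i in range(n_puncta)],
        "psf_sigma_px": sigma_px,
        "amplitude": amplitude,
        "noise_sd": noise_sd,
    }
    return img, truth
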