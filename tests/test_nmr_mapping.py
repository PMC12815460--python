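"""Tests for attenuation/CSP profiles, significance rules and region segmentation."""

import math

import numpy as np
import pytest

from endoquant.equilibrium import fit_kd, predicted_response
from endoquant.errors import EmptyOverlapError, InvalidParameterError
from endoquant.nmr_mapping import (
    AtomGroup,
    BindingRegion,
    PeakList,
    Resonance,
    combined_csp,
    extract_titration,
    intensity_ratios,
    segment_regions,
)
from endoquant.synthetic import gen_peaklist_pair


def simple_pair(make_peaklist, intensities_bound, intensities_apo=None, n=None):
    n = n or len(intensities_bound)
    apo_int = intensities_apo or [100.0] * n
    apo = make_peaklist([(i + 1, "A", 8.0, 120.0, apo_int[i]) for i in range(n)])
    bound = make_peaklist([(i + 1, "A", 8.0, 120.0, intensities_bound[i]) for i in range(n)])
    return apo, bound


class TestIntensityRatios:
    def test_identical_lists_nothing_significant(self, make_peaklist):
        apo, bound = simple_pair(make_peaklist, [100.0] * 5)
        profile = intensity_ratios(apo, bound)
        assert all(v == 1.0 for v in profile.entries.values())
        assert profile.sd == 0.0
        assert profile.significant == frozenset()  # strict inequality at sd = 0

    def test_hand_computed_threshold(self, make_peaklist):
        # ratios {1, 1, 1, 0.2}: mean 0.8, sample SD 0.4, threshold 0.4
        apo, bound = simple_pair(make_peaklist, [100.0, 100.0, 100.0, 20.0])
        profile = intensity_ratios(apo, bound)
        assert profile.mean == pytest.approx(0.8)
        assert profile.sd == pytest.approx(0.4)
        assert profile.threshold == pytest.approx(0.4)
        assert profile.significant == frozenset({4})

    def test_zero_apo_intensity_excluded_not_fatal(self, make_peaklist):
        apo = make_peaklist([(1, "A", 8.0, 120.0, 0.0), (2, "A", 8.1, 121.0, 100.0),
                             (3, "A", 8.2, 122.0, 100.0)])
        bound = make_peaklist([(1, "A", 8.0, 120.0, 50.0), (2, "A", 8.1, 121.0, 80.0),
                               (3, "A", 8.2, 122.0, 100.0)])
        profile = intensity_ratios(apo, bound)
        assert 1 not in profile.entries
        assert profile.excluded == ((1, "zero apo intensity"),)

    def test_no_shared_keys_raises(self, make_peaklist):
        apo = make_peaklist([(1, "A", 8.0, 120.0, 100.0)])
        bound = make_peaklist([(2, "A", 8.0, 120.0, 100.0)])
        with pytest.raises(EmptyOverlapError):
            intensity_ratios(apo, bound)

    def test_keys_restricted_to_intersection(self, make_peaklist):
        apo = make_peaklist([(i, "A", 8.0, 120.0, 100.0) for i in (1, 2, 3)])
        bound = make_peaklist([(i, "A", 8.0, 120.0, 90.0) for i in (2, 3, 4)])
        profile = intensity_ratios(apo, bound)
        assert set(profile.entries) == {2, 3}

    def test_significance_invariant_under_uniform_rescaling(self, make_peaklist, rng):
        ints = list(rng.uniform(20, 200, 30))
        bound_ints = [v * r for v, r in zip(ints, rng.uniform(0.1, 1.1, 30))]
        apo, bound = simple_pair(make_peaklist, bound_ints, intensities_apo=ints)
        base = intensity_ratios(apo, bound)
        apo2, bound2 = simple_pair(
            make_peaklist, [5.0 * v for v in bound_ints], intensities_apo=ints
        )
        scaled = intensity_ratios(apo2, bound2)
        assert scaled.significant == base.significant


class TestCombinedCSP:
    def test_formula_forced_values(self, make_peaklist):
        apo = make_peaklist([(1, "I", 1.0, 13.6, 100.0), (2, "I", 1.02, 10.10, 100.0),
                             (3, "I", 1.0, 10.0, 100.0)],
                            atom_group=AtomGroup.ile_d1_methyl)
        bound = make_peaklist([(1, "I", 1.0, 10.0, 100.0), (2, "I", 1.0, 10.0, 100.0),
                               (3, "I", 1.0, 10.0, 100.0)],
                              atom_group=AtomGroup.ile_d1_methyl)
        profile = combined_csp(apo, bound)
        assert profile.entries[1] == pytest.approx(1.0)  # dH=0, dC=3.6 -> 1.0 ppm
        assert profile.entries[2] == pytest.approx(0.0342, abs=5e-5)
        assert profile.entries[3] == 0.0

    def test_missing_shift_excluded(self, make_peaklist):
        apo = make_peaklist([(1, "A", math.nan, 120.0, 100.0), (2, "A", 8.0, 120.0, 100.0),
                             (3, "A", 8.0, 121.0, 100.0)])
        bound = make_peaklist([(1, "A", 8.0, 120.0, 100.0), (2, "A", 8.05, 120.0, 100.0),
                               (3, "A", 8.0, 121.0, 100.0)])
        profile = combined_csp(apo, bound)
        assert 1 not in profile.entries
        assert profile.excluded == ((1, "missing shift"),)

    def test_significance_invariant_under_common_offset(self, make_peaklist, rng):
        shifts_h = rng.uniform(7, 9, 20)
        shifts_x = rng.uniform(105, 130, 20)
        perturb = np.where(np.arange(20) < 3, 0.3, 0.0) + rng.normal(0, 0.005, 20)
        apo = make_peaklist(
            [(i + 1, "A", float(shifts_h[i]), float(shifts_x[i]), 100.0) for i in range(20)]
        )
        bound = make_peaklist(
            [(i + 1, "A", float(shifts_h[i] - perturb[i]), float(shifts_x[i]), 100.0)
             for i in range(20)]
        )
        base = combined_csp(apo, bound)
        offset = 0.37
        apo_off = make_peaklist(
            [(i + 1, "A", float(shifts_h[i] + offset), float(shifts_x[i] + offset), 100.0)
             for i in range(20)]
        )
        bound_off = make_peaklist(
            [(i + 1, "A", float(shifts_h[i] - perturb[i] + offset),
              float(shifts_x[i] + offset), 100.0) for i in range(20)]
        )
        assert combined_csp(apo_off, bound_off).significant == base.significant


class TestSegmentRegions:
    @pytest.mark.parametrize(
        "residues, max_gap, expected",
        [
            ({374, 375, 376, 377, 378, 379, 380, 381}, 0, [(374, 381)]),
            ({39, 40, 48, 49, 50}, 0, [(39, 40), (48, 50)]),
            ({10, 12}, 1, [(10, 12)]),
            ({10, 12}, 0, [(10, 10), (12, 12)]),
            (set(), 0, []),
        ],
    )
    def test_segmentation(self, residues, max_gap, expected):
        regions = segment_regions(residues, max_gap=max_gap)
        assert [(r.start_residue, r.end_residue) for r in regions] == expected

    def test_region_string_convention(self):
        assert str(BindingRegion(374, 381)) == "374-381"
        assert str(BindingRegion(108, 108)) == "108"


class TestPlantedSiteRecovery:
    def test_noiseless_recovery_exact(self):
        site = BindingRegion(374, 381)
        apo, bound, truth = gen_peaklist_pair(
            n_residues=393, site=site, attenuation_depth=0.8, csp_peak=0.05,
            noise_sd=0.0, seed=0,
        )
        profile = intensity_ratios(apo, bound)
        assert segment_regions(profile.significant) == [site]
        csp = combined_csp(apo, bound)
        assert segment_regions(csp.significant) == [site]

    def test_zero_depth_nothing_significant(self):
        apo, bound, _ = gen_peaklist_pair(
            n_residues=100, site=BindingRegion(40, 47), attenuation_depth=0.0,
            csp_peak=0.0, noise_sd=0.0, seed=1,
        )
        profile = intensity_ratios(apo, bound)
        assert profile.significant == frozenset()


class TestExtractTitration:
    KEY = (377, AtomGroup.ile_d1_methyl)

    @staticmethod
    def methyl_lists(shifts_x):
        return [
            PeakList(
                condition_label=f"L{ligand}",
                resonances=(
                    Resonance(377, "I", AtomGroup.ile_d1_methyl, 0.8, sx, 100.0),
                ),
            )
            for ligand, sx in shifts_x
        ]

    def test_identical_lists_zero_response(self):
        lists = self.methyl_lists([(0.0, 12.5), (100.0, 12.5)])
        series = extract_titration(
            list(zip([0.0, 100.0], lists)), self.KEY, protein_total=50.0
        )
        assert list(series.responses) == [0.0, 0.0]

    def test_round_trip_through_fit(self):
        ligands = np.linspace(0.0, 600.0, 8)
        shifts = 12.5 - predicted_response(50.0, ligands, 104.0, 0.18)
        lists = self.methyl_lists(list(zip(ligands, shifts)))
        series = extract_titration(
            list(zip(ligands, lists)), self.KEY, protein_total=50.0
        )
        result = fit_kd(series)
        assert result.kd == pytest.approx(104.0, rel=1e-6)

    def test_missing_zero_point_rejected(self):
        lists = self.methyl_lists([(50.0, 12.4), (100.0, 12.3)])
        with pytest.raises(InvalidParameterError):
            extract_titration(list(zip([50.0, 100.0], lists)), self.KEY, protein_total=50.0)

    def test_single_point_series_passes_through(self):
        lists = self.methyl_lists([(0.0, 12.5)])
        series = extract_titration(list(zip([0.0], lists)), self.KEY, protein_total=50.0)
        assert len(series) == 1
        with pytest.raises(InvalidParameterError):
            fit_kd(series)
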