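import numpy as np
import pytest

from endoquant.nmr_mapping import AtomGroup, PeakList, Resonance


@pytest.fixture
def make_peaklist():
    """Factory for peak lists from (residue, type, shift_h, shift_x, intensity) rows."""

    def _make(rows, label="test", atom_group=AtomGroup.backbone_amide):
        resonances = tuple(
            Resonance(
                residue_number=r,
                residue_type=t,
                atom_group=atom_group,
                shift_h=sh,
                shift_x=sx,
                intensity=i,
            )
            for r, t, sh, sx, i in rows
        )
        return PeakList(condition_label=label, resonances=resonances)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
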