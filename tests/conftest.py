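import numpy as np
import pytest

from allonmr import simulate
from allonmr.peaklist import (
    AtomGroup,
    NucleusClass,
    PeakEntry,
    PeakList,
    ResonanceKey,
    StateSet,
)


def make_peaklist(state_id, shifts, nucleus_class=NucleusClass.HN_N, heights=None):
    """Build a peak list from {residue_number: (shift_h, shift_x)}; type G."""
    pl = PeakList(state_id=state_id, nucleus_class=nucleus_class)
    for i, (num, (h, x)) in enumerate(sorted(shifts.items())):
        height = 100.0 if heights is None else heights[num]
        pl.add(ResonanceKey(num, "G", AtomGroup.backbone_amide),
               PeakEntry(shift_h=h, shift_x=x, height=height))
    return pl


@pytest.fixture
def two_state_spec():
    return simulate.TwoStateSpec(seed=11)


@pytest.fixture
def state_set(two_state_spec):
    return simulate.simulate_states(two_state_spec)


@pytest.fixture
def active_structure(tmp_path):
    from allonmr import geometry

    path = tmp_path / "active.pdb"
    path.write_text(simulate.make_structure_fixture("active_like"))
    return geometry.load_structure(path, chain="A")


@pytest.fixture
def inhibited_structure(tmp_path):
    from allonmr import geometry

    path = tmp_path / "inhibited.pdb"
    path.write_text(simulate.make_structure_fixture("inhibited_like"))
    return geometry.load_structure(path, chain="A")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
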