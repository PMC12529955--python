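import numpy as np
import pytest

from monolayer.traj import Frame


@pytest.fixture
def point_frame_factory():
    """Frames of single-atom molecules at given xy positions (COM = atom)."""

    def make(xy, box=(8.0, 8.0, 25.5), mol_type="X", z=10.0):
        xy = np.asarray(xy, dtype=float)
        n = xy.shape[0]
        pos = np.column_stack([xy, np.full(n, z)])
        return Frame(
            positions=pos,
            box=np.asarray(box, dtype=float),
            mol_ids=np.arange(n),
            mol_types=np.array([mol_type] * n, dtype=object),
            atom_names=np.array(["C1"] * n, dtype=object),
        )

    return make
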