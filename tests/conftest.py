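import numpy as np
import pytest

import memstab
from memstab import fixtures as fx


@pytest.fixture(scope="session")
def bundle():
    """Seven-helix bundle with two low-confidence dips, fixed seed."""
    return fx.make_helix_bundle(
        seed=1, plddt_dips=[(40, 48, 70.0), (120, 126, 55.0)]
    )


@pytest.fixture(scope="session")
def bundle_tm_ranges():
    return fx.tm_ranges_for_bundle(7, 30)


@pytest.fixture(scope="session")
def planted_msa(bundle):
    """50-row homolog alignment with tolerated substitutions at 3 positions."""
    tolerated = {
        pos: "".join(a for a in aas if a != bundle.sequence[pos - 1])
        for pos, aas in {10: "AS", 75: "ILV", 150: "FY"}.items()
    }
    aln, planted = fx.make_msa(bundle.sequence, n_rows=50, tolerated=tolerated, seed=1)
    return aln, planted


@pytest.fixture(scope="session")
def slab_frame():
    """Membrane slab centered at the origin, normal +z, half-thickness 15 A."""
    return memstab.MembraneFrame(np.zeros(3), np.array([0.0, 0.0, 1.0]), 15.0)
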