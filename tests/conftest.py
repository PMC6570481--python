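import numpy as np
import pandas as pd
import pytest

from kinmotif.alphabet import GRID_RESIDUES, POSITIONS
from kinmotif.opls import MotifMatrix, SpotGrid


def make_grid(values: np.ndarray, kinase="NekX", library="ST", replicate="rep1", acceptor=None):
    flank = pd.DataFrame(values, index=pd.Index(POSITIONS, name="position"), columns=list(GRID_RESIDUES))
    acc = pd.Series(acceptor, index=["S", "T", "Y"]) if acceptor is not None else None
    return SpotGrid(kinase_id=kinase, library=library, replicate_id=replicate, flank=flank, acceptor=acc)


def make_motif(values: np.ndarray, stage="normalized", kinase="NekX", library="ST", **kw):
    df = pd.DataFrame(values, index=pd.Index(POSITIONS, name="position"), columns=list(GRID_RESIDUES))
    return MotifMatrix(kinase_id=kinase, library=library, stage=stage, values=df, **kw)


@pytest.fixture
def random_grid():
    rng = np.random.default_rng(42)
    return make_grid(rng.uniform(0.5, 20.0, size=(9, 22)), acceptor=[12.0, 6.0, 2.0])


@pytest.fixture
def flat_motif():
    """All-ones motif at the capped stage: no residue favored anywhere."""
    return make_motif(np.ones((9, 22)), stage="capped")
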