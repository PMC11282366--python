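import numpy as np
import pandas as pd
import pytest

from gradeshift import tree_io
from gradeshift.grades import GradeScheme, TipPriorMatrix


@pytest.fixture
def make_tree(tmp_path):
    """Parse a Newick string into a Phylogeny via the package reader."""

    def _make(newick: str, fmt: str = "newick"):
        ext = "nwk" if fmt == "newick" else "nex"
        p = tmp_path / f"tree_{abs(hash(newick)) % 10**8}.{ext}"
        p.write_text(newick if newick.endswith("\n") else newick + "\n")
        return tree_io.read_tree(str(p), format=fmt)

    return _make


@pytest.fixture
def tree3(make_tree):
    return make_tree("((A:1.0,B:1.0):1.0,C:2.0);")


@pytest.fixture
def tree4(make_tree):
    return make_tree("((A:1,B:1):0.5,(C:0.7,D:0.8):1.2);")


def priors_from_rows(tree, rows, states=None):
    rows = np.asarray(rows, dtype=float)
    states = tuple(range(rows.shape[1])) if states is None else tuple(states)
    df = pd.DataFrame(rows, index=list(tree.tip_labels), columns=list(states))
    return TipPriorMatrix(df, GradeScheme(states=states))
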