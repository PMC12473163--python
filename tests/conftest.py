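import numpy as np
import pytest

from markerscreen.seq_core import LocusAlignment, Sequence


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_alignment(rows: dict[str, str], name: str = "toy") -> LocusAlignment:
    return LocusAlignment(name, tuple(Sequence(t, s) for t, s in rows.items()))


@pytest.fixture
def toy_alignment():
    return make_alignment(
        {"r1": "AC--GT", "r2": "ACTTGT", "r3": "AC--GT"}
    )


def random_alignment(rng, n_taxa, n_cols, gap_frac=0.1, name="rand"):
    """Random alignment over ACGT,-,N for oracle-equivalence tests."""
    alphabet = np.array(list("ACGT-N"))
    probs = np.array(
        [(1 - gap_frac - 0.02) / 4] * 4 + [gap_frac, 0.02]
    )
    mat = rng.choice(alphabet, size=(n_taxa, n_cols), p=probs / probs.sum())
    rows = {}
    for i in range(n_taxa):
        row = "".join(mat[i])
        if set(row) <= {"-", "N"}:  # keep Sequence invariant satisfied
            row = "A" + row[1:]
        rows[f"t{i}"] = row
    return make_alignment(rows, name)
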