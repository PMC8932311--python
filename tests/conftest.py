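import numpy as np
import pytest

from msaclean.alignment import Alignment
from msaclean.synthetic import DefectPlan, Insertion, RaggedEnd, generate


def make_alignment(rows, names=None, alphabet="nucleotide"):
    names = names or [f"s{i}" for i in range(len(rows))]
    matrix = np.array([list(r) for r in rows], dtype="<U1")
    return Alignment(names, matrix, alphabet)


def random_alignment(rng, n_rows=None, n_cols=None, gap_prob=0.25,
                     alphabet="nucleotide"):
    """Unstructured random alignment (noise, not a plausible MSA)."""
    n_rows = n_rows or int(rng.integers(3, 13))
    n_cols = n_cols or int(rng.integers(5, 41))
    residues = list("ACGT") if alphabet == "nucleotide" else list("ACDEFGHIKL")
    chars = np.array(residues + ["-"])
    probs = [(1 - gap_prob) / len(residues)] * len(residues) + [gap_prob]
    matrix = rng.choice(chars, size=(n_rows, n_cols), p=probs)
    return make_alignment(["".join(r) for r in matrix], alphabet=alphabet)


def random_plan(rng, seed):
    """A structured plan with a random mix of planted defects."""
    n_rows = int(rng.integers(6, 11))
    n_cols = int(rng.integers(90, 150))
    plan = DefectPlan(n_rows=n_rows, n_cols=n_cols, seed=seed)
    rows = list(rng.permutation(n_rows))
    if rng.random() < 0.7:
        plan.divergent_rows = [(int(rows.pop()), float(rng.uniform(0.3, 0.55)))]
    if rng.random() < 0.7:
        width = int(rng.integers(3, 9))
        start = int(rng.integers(n_cols // 3, n_cols // 2))
        plan.insertions = [Insertion(start, width, (int(rows.pop()),))]
    if rng.random() < 0.7:
        plan.ragged_ends = [
            RaggedEnd(int(rows.pop()), "start", int(rng.integers(1, 4)), 8)
        ]
    if rng.random() < 0.7:
        plan.short_rows = [(int(rows.pop()), int(rng.integers(5, 20)))]
    if rng.random() < 0.7:
        # near the far end: outside ragged windows, insertions and flanks
        plan.gaponly_cols = [n_cols - int(rng.integers(5, 15))]
    return plan


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy():
    """Five near-identical rows over 20 columns, no defects."""
    row = "ACGTACGTACGTACGTACGT"
    return make_alignment([row] * 5)


@pytest.fixture
def structured(rng):
    plan = random_plan(rng, seed=4)
    return generate(plan)
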