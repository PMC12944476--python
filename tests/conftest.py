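import numpy as np
import pytest

from pstfst import MarkerMatrix, make_paper_fixture


@pytest.fixture(scope="session")
def paper_tables():
    """Published trait summaries, site table and pairwise F_ST matrix."""
    return make_paper_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def toy_marker_matrix(q_by_pop, n_per_pop, rng, locus_prefix="L"):
    """Markers drawn at fixed per-population band-absent allele
    frequencies (one column per locus), HWE within populations."""
    q = np.asarray(q_by_pop, dtype=float)  # pops x loci
    k, loci = q.shape
    rows, labels = [], []
    for i in range(k):
        absent = rng.random((n_per_pop, loci)) < q[i] ** 2
        rows.append((~absent).astype(float))
        labels += [f"pop{i + 1}"] * n_per_pop
    bands = np.vstack(rows)
    return MarkerMatrix(
        individual_ids=[f"ind{i}" for i in range(bands.shape[0])],
        population_labels=labels,
        locus_ids=[f"{locus_prefix}{j + 1}" for j in range(loci)],
        bands=bands,
    )


@pytest.fixture
def opposite_fixed_markers():
    """Two populations fixed for opposite bands at every locus: maximal
    differentiation (F_ST = 1)."""
    bands = np.vstack([np.zeros((8, 10)), np.ones((8, 10))])
    return MarkerMatrix(
        individual_ids=[f"i{i}" for i in range(16)],
        population_labels=["A"] * 8 + ["B"] * 8,
        locus_ids=[f"L{j}" for j in range(10)],
        bands=bands,
    )
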