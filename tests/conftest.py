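"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import random

import dendropy
import numpy as np
import pytest

from ssrdup.distances import DistanceResult
from ssrdup.matrix import ABSENT, BandMatrix, MISSING, PRESENT


def brute_force_distances(m: BandMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell double-loop recount of differences and compared bands.

    Deliberately naive: iterates every pair and every column, independent of
    the vectorised implementation it checks.
    """
    n, ncol = m.cells.shape
    diff = np.zeros((n, n), dtype=int)
    comp = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            if i == j:
                comp[i, j] = int((m.cells[i] != MISSING).sum())
                continue
            for c in range(ncol):
                a, b = m.cells[i, c], m.cells[j, c]
                if a == MISSING or b == MISSING:
                    continue
                comp[i, j] += 1
                if a != b:
                    diff[i, j] += 1
    return diff, comp


def random_band_matrix(
    seed: int, n: int = 6, m: int = 12, missing_rate: float = 0.1
) -> BandMatrix:
    rng = np.random.default_rng(seed)
    cells = rng.choice(
        [PRESENT, ABSENT, MISSING],
        size=(n, m),
        p=[(1 - missing_rate) / 2, (1 - missing_rate) / 2, missing_rate],
    ).astype(np.int8)
    # guarantee every pair keeps at least one mutually scored column
    cells[:, 0] = PRESENT
    return BandMatrix(
        [f"A{i:02d}" for i in range(n)], [f"F{j:02d}" for j in range(m)], cells
    )


def distance_result(labels: list[str], D: np.ndarray, total: int | None = None) -> DistanceResult:
    D = np.asarray(D)
    total = total if total is not None else int(D.max()) + 1
    return DistanceResult(
        accession_ids=list(labels),
        diff_counts=D.astype(int),
        compared_counts=np.full_like(D, total, dtype=int),
        total_bands=total,
    )


def random_additive_tree(
    n_leaves: int, seed: int
) -> tuple[dendropy.Tree, list[str], np.ndarray, dendropy.TaxonNamespace]:
    """Random tree with integer branch lengths and its exact leaf distances."""
    from dendropy.simulate import treesim

    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace([f"T{i}" for i in range(n_leaves)])
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_leaves,
        taxon_namespace=tns,
        rng=random.Random(seed),
    )
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length = float(rng.integers(1, 10))
    pdm = tree.phylogenetic_distance_matrix()
    labels = [t.label for t in tns]
    D = np.zeros((n_leaves, n_leaves))
    for i, j in itertools.combinations(range(n_leaves), 2):
        D[i, j] = D[j, i] = pdm.distance(
            tns.get_taxon(labels[i]), tns.get_taxon(labels[j])
        )
    return tree, labels, D, tns


@pytest.fixture
def tiny_matrix() -> BandMatrix:
    """3 accessions x 4 fragments with one missing cell."""
    cells = np.array(
        [
            [PRESENT, PRESENT, ABSENT, PRESENT],
            [PRESENT, MISSING, ABSENT, ABSENT],
            [ABSENT, PRESENT, PRESENT, PRESENT],
        ],
        dtype=np.int8,
    )
    return BandMatrix(["A", "B", "C"], ["f1", "f2", "f3", "f4"], cells)
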