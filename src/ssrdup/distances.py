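"""Pairwise band-difference counts under pairwise deletion.

The distance between two accessions is the number of fragment columns at
which one shows the band and the other does not, counted only over columns
scored (non-missing) in *both* accessions — "pairwise deletion" of missing
data.  The divergence proportion divides the raw count by the fixed total
number of bands in the matrix, not by the per-pair compared count, so that a
single mismatch always represents the same fraction of the fingerprint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .matrix import ABSENT, BandMatrix, PRESENT


class DistanceError(ValueError):
    """Raised when a pairwise distance is undefined or inputs are invalid."""


@dataclass
class DistanceResult:
    """Difference and compared-band counts for every accession pair.

    Attributes
    ----------
    accession_ids
        Row/column order of both matrices.
    diff_counts
        Symmetric integer matrix of band mismatches, zero diagonal.
    compared_counts
        Symmetric integer matrix of bands non-missing in both members.
    total_bands
        The fixed fragment count of the source matrix, used as the
        denominator of divergence proportions.
    """

    accession_ids: list[str]
    diff_counts: np.ndarray
    compared_counts: np.ndarray
    total_bands: int

    @property
    def n(self) -> int:
        return len(self.accession_ids)

    def pair(self, a: str, b: str) -> tuple[int, int]:
        """(differences, compared bands) for one accession pair."""
        i = self.accession_ids.index(a)
        j = self.accession_ids.index(b)
        return int(self.diff_counts[i, j]), int(self.compared_counts[i, j])


@dataclass
class DifferenceHistogram:
    """Counts of accession pairs per difference value."""

    counts: dict[int, int]
    n_pairs: int

    def pairs_at_most(self, t: int) -> int:
        return sum(c for d, c in self.counts.items() if d <= t)


def pairwise_differences(m: BandMatrix) -> DistanceResult:
    """Count band mismatches for every unordered accession pair.

    Columns missing in either member of a pair are excluded from that pair's
    comparison.  A pair with no mutually scored column has no defined
    distance and raises :class:`DistanceError` naming the pair.
    """
    present = (m.cells == PRESENT).astype(np.int32)
    absent = (m.cells == ABSENT).astype(np.int32)
    diff = present @ absent.T
    diff = diff + diff.T
    scored = present + absent
    compared = scored @ scored.T
    np.fill_diagonal(diff, 0)

    bad = (compared == 0) & ~np.eye(m.n_accessions, dtype=bool)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise DistanceError(
            f"accessions {m.accession_ids[i]!r} and {m.accession_ids[j]!r} "
            "share no mutually scored band; their distance is undefined"
        )
    return DistanceResult(
        accession_ids=list(m.accession_ids),
        diff_counts=diff,
        compared_counts=compared,
        total_bands=m.n_fragments,
    )


def proportion_matrix(
    d: DistanceResult, denominator: str = "total"
) -> np.ndarray:
    """Divergence proportions per pair.

    ``denominator="total"`` (the default) divides every difference count by
    the fixed total band number; ``"compared"`` divides by the per-pair
    compared count instead (an alternative normalisation, not the default).
    """
    if d.total_bands <= 0:
        raise DistanceError("total_bands must be positive")
    if denominator == "total":
        return d.diff_counts / float(d.total_bands)
    if denominator == "compared":
        return d.diff_counts / d.compared_counts.astype(float)
    raise ValueError(f"unknown denominator {denominator!r}")


def _upper(d: DistanceResult) -> np.ndarray:
    iu = np.triu_indices(d.n, 1)
    return d.diff_counts[iu]


def difference_histogram(d: DistanceResult) -> DifferenceHistogram:
    """Histogram of difference counts over all unordered pairs."""
    values, counts = np.unique(_upper(d), return_counts=True)
    n = d.n
    return DifferenceHistogram(
        counts={int(v): int(c) for v, c in zip(values, counts)},
        n_pairs=n * (n - 1) // 2,
    )


def mean_difference(d: DistanceResult) -> float:
    """Arithmetic mean difference count over all unordered pairs."""
    if d.n < 2:
        raise DistanceError("need at least 2 accessions for a mean difference")
    return float(_upper(d).mean())


def write_square_csv(d: DistanceResult, path: str | Path) -> None:
    """Square difference-count matrix as labelled CSV."""
    pd.DataFrame(
        d.diff_counts, index=d.accession_ids, columns=d.accession_ids
    ).to_csv(path, index_label="accession_id")


def write_phylip(d: DistanceResult, path: str | Path) -> None:
    """Square PHYLIP distance format (relaxed names, tab separated)."""
    lines = [f"{d.n}"]
    for name, row in zip(d.accession_ids, d.diff_counts):
        lines.append(name + "\t" + "\t".join(str(int(x)) for x in row))
    Path(path).write_text("\n".join(lines) + "\n")


def write_histogram_csv(h: DifferenceHistogram, path: str | Path) -> None:
    frame = pd.DataFrame(
        sorted(h.counts.items()), columns=["differences", "n_pairs"]
    )
    frame.to_csv(path, index=False)
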