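"""Synthetic dominant-SSR fingerprint collections with planted clonal groups.

The generator emulates a clonally propagated tetraploid collection typed at
~60 SSR loci scored as dominant bands: each locus has a pool of 3-12 possible
alleles (fragments) with skewed population frequencies, each unique genotype
carries 1-4 of them, clonal duplicates of a founder genotype differ from it
by a handful of band flips (scoring error / somatic mutation), and a small
fraction of cells is missing.  Defaults mirror a 198-accession Nordic potato
collection: 140 unique genotypes of which 31 found clonal groups sized
21x2 + 4x3 + 3x4 + 1x5 + 8 + 10 (89 grouped accessions, 109 singletons).

Allele frequencies per locus are Dirichlet(alpha) with a small concentration
(default 0.2), which makes a few alleles common and the rest rare; sampling
genotype bands by those weights yields between-genotype distances mostly in
the 70-140 band range with a mean near 105 of ~470 bands — the regime of a
real clonal collection, where independent genotypes share frequent alleles.
The realised within/between separation is measured, not assumed; see
:func:`realized_gap`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .matrix import ABSENT, AccessionRecord, BandMatrix, MISSING, PRESENT


class SimulationError(ValueError):
    """Raised for infeasible simulation configurations."""


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults are the study-scale collection above.

    ``within_clone_flip_range`` bounds (inclusive) the number of band flips
    separating a clone-group member from its founder; its upper bound must
    stay well below typical between-genotype distances or the planted
    within/between gap disappears.
    """

    n_loci: int = 62
    alleles_per_locus: tuple[int, int] = (3, 12)
    bands_per_genotype: tuple[int, int] = (1, 4)
    n_unique_genotypes: int = 140
    group_size_distribution: Mapping[int, int] = field(
        default_factory=lambda: {2: 21, 3: 4, 4: 3, 5: 1, 8: 1, 10: 1}
    )
    within_clone_flip_range: tuple[int, int] = (0, 5)
    missing_rate: float = 0.01
    allele_concentration: float = 0.2
    seed: int = 0

    def n_groups(self) -> int:
        return sum(self.group_size_distribution.values())

    def n_accessions(self) -> int:
        extra = sum(
            (size - 1) * count
            for size, count in self.group_size_distribution.items()
        )
        return self.n_unique_genotypes + extra

    def validate(self) -> None:
        if self.n_loci < 1 or self.n_unique_genotypes < 2:
            raise SimulationError("need at least 1 locus and 2 unique genotypes")
        lo, hi = self.alleles_per_locus
        if not 1 <= lo <= hi:
            raise SimulationError("invalid alleles_per_locus range")
        blo, bhi = self.bands_per_genotype
        if not 1 <= blo <= bhi:
            raise SimulationError("invalid bands_per_genotype range")
        flo, fhi = self.within_clone_flip_range
        if not 0 <= flo <= fhi:
            raise SimulationError("invalid within_clone_flip_range")
        if not 0.0 <= self.missing_rate < 1.0:
            raise SimulationError("missing_rate must be in [0, 1)")
        if any(s < 2 for s in self.group_size_distribution):
            raise SimulationError("clonal groups must have size >= 2")
        if self.n_groups() > self.n_unique_genotypes:
            raise SimulationError(
                "more clonal groups requested than unique genotypes"
            )


@dataclass
class SyntheticTruth:
    """Ground truth emitted with a simulated matrix."""

    genotype_of: dict[str, str]
    groups: list[list[str]]

    def cluster_sets(self) -> set[frozenset[str]]:
        """Planted groups in the shape duplicate calling reports."""
        return {frozenset(g) for g in self.groups}


def truth_clusters(t: SyntheticTruth) -> set[frozenset[str]]:
    """Planted clonal groups as member sets, comparable to a called census."""
    return t.cluster_sets()


def perturb_clone(
    genotype_bands: np.ndarray, n_flips: int, rng: np.random.Generator
) -> np.ndarray:
    """Toggle exactly ``n_flips`` distinct band positions of a fingerprint."""
    if n_flips < 0:
        raise SimulationError("n_flips must be >= 0")
    bands = np.asarray(genotype_bands, dtype=bool)
    if n_flips > bands.size:
        raise SimulationError("cannot flip more positions than the vector has")
    out = bands.copy()
    pos = rng.choice(bands.size, size=n_flips, replace=False)
    out[pos] = ~out[pos]
    return out


def _locus_pools(cfg: SimConfig, rng: np.random.Generator) -> list[np.ndarray]:
    lo, hi = cfg.alleles_per_locus
    pools = []
    for _ in range(cfg.n_loci):
        k = int(rng.integers(lo, hi + 1))
        w = rng.dirichlet(np.full(k, cfg.allele_concentration)) + 1e-9
        pools.append(w / w.sum())
    return pools


def generate_collection(cfg: SimConfig) -> tuple[BandMatrix, SyntheticTruth]:
    """Simulate a band matrix plus its ground truth.

    Every unique genotype draws, independently per locus, 1-4 alleles from
    that locus's pool (frequency-weighted, without replacement).  Each clonal
    group consists of one founder accession plus copies perturbed by a
    founder-to-copy flip count drawn uniformly from
    ``within_clone_flip_range``; missing cells are then sprinkled uniformly.
    Accession order is shuffled so groups are not file-contiguous.  Fully
    deterministic given ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    pools = _locus_pools(cfg, rng)

    fragment_ids: list[str] = []
    loci: list[str] = []
    for l, w in enumerate(pools):
        marker = f"SSR{l + 1:02d}"
        for a in range(w.size):
            fragment_ids.append(f"{marker}_{150 + 2 * a}")
            loci.append(marker)
    n_cols = len(fragment_ids)

    blo, bhi = cfg.bands_per_genotype
    genotypes = np.zeros((cfg.n_unique_genotypes, n_cols), dtype=bool)
    col0 = 0
    for w in pools:
        k = w.size
        for g in range(cfg.n_unique_genotypes):
            d = int(rng.integers(blo, min(bhi, k) + 1))
            chosen = rng.choice(k, size=d, replace=False, p=w)
            genotypes[g, col0 + chosen] = True
        col0 += k

    sizes: list[int] = []
    for size in sorted(cfg.group_size_distribution, reverse=True):
        sizes.extend([size] * cfg.group_size_distribution[size])
    founders = rng.choice(cfg.n_unique_genotypes, size=len(sizes), replace=False)

    flo, fhi = cfg.within_clone_flip_range
    rows: list[np.ndarray] = []
    genotype_of: dict[int, int] = {}  # row index -> genotype index
    group_rows: list[list[int]] = []
    copies = {int(f): s - 1 for f, s in zip(founders, sizes)}
    for g in range(cfg.n_unique_genotypes):
        first = len(rows)
        rows.append(genotypes[g])
        genotype_of[first] = g
        if g in copies:
            members = [first]
            for _ in range(copies[g]):
                flips = int(rng.integers(flo, fhi + 1))
                idx = len(rows)
                rows.append(perturb_clone(genotypes[g], flips, rng))
                genotype_of[idx] = g
                members.append(idx)
            group_rows.append(members)

    n = len(rows)
    cells = np.where(np.vstack(rows), PRESENT, ABSENT).astype(np.int8)
    if cfg.missing_rate > 0:
        cells[rng.random(cells.shape) < cfg.missing_rate] = MISSING

    order = rng.permutation(n)
    cells = cells[order]
    rank = {int(old): new for new, old in enumerate(order)}
    ids = [f"ACC-{i + 1:03d}" for i in range(n)]
    truth = SyntheticTruth(
        genotype_of={
            ids[rank[row]]: f"G-{genotype_of[row] + 1:03d}" for row in range(n)
        },
        groups=[sorted(ids[rank[r]] for r in grp) for grp in group_rows],
    )
    matrix = BandMatrix(ids, fragment_ids, cells, loci=loci)
    return matrix, truth


def generate_metadata(
    truth: SyntheticTruth, cfg: SimConfig
) -> dict[str, AccessionRecord]:
    """Plausible passport records for a simulated collection.

    Collections and countries are drawn with frequencies echoing a
    three-genebank Nordic collection; names are synthetic variety names that
    duplicate-group members do NOT share, mimicking synonymous naming.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    collections = np.array(["LKF-Vandel", "NordGen", "NGS"])
    coll_p = np.array([43, 90, 65], dtype=float)
    coll_p /= coll_p.sum()
    countries = np.array(["Sweden", "Norway", "Denmark", "Finland", "Iceland", "other"])
    country_p = np.array([0.3, 0.25, 0.2, 0.1, 0.05, 0.1])
    types = np.array(["landrace", "improved variety", "breeding line"])
    type_p = np.array([0.45, 0.45, 0.10])

    records: dict[str, AccessionRecord] = {}
    for acc in sorted(truth.genotype_of):
        records[acc] = AccessionRecord(
            accession_id=acc,
            name=f"Sort {acc.split('-')[-1]}",
            collection=str(rng.choice(collections, p=coll_p)),
            country=str(rng.choice(countries, p=country_p)),
            clonal_type=str(rng.choice(types, p=type_p)),
        )
    return records


def write_truth_csv(truth: SyntheticTruth, path) -> None:
    """Truth sidecar: accession_id, genotype_label, group_id (blank if none)."""
    import pandas as pd

    group_of = {}
    for k, grp in enumerate(truth.groups, start=1):
        for a in grp:
            group_of[a] = f"T-{k}"
    pd.DataFrame(
        [
            {
                "accession_id": a,
                "genotype_label": g,
                "group_id": group_of.get(a, ""),
            }
            for a, g in sorted(truth.genotype_of.items())
        ]
    ).to_csv(path, index=False)


def realized_gap(
    m: BandMatrix, truth: SyntheticTruth
) -> dict[str, float | int | None]:
    """Measure the realised within-group vs between-genotype separation.

    Returns the maximum within-planted-group difference, the minimum
    between-genotype difference, and whether the configured gap held (every
    within-group pair closer than every between-genotype pair).
    """
    from .distances import pairwise_differences

    d = pairwise_differences(m)
    idx = {a: i for i, a in enumerate(d.accession_ids)}
    n = d.n
    same = np.zeros((n, n), dtype=bool)
    for grp in truth.groups:
        for a in grp:
            for b in grp:
                same[idx[a], idx[b]] = True
    iu = np.triu_indices(n, 1)
    within = d.diff_counts[iu][same[iu]]
    between = d.diff_counts[iu][~same[iu]]
    max_within = int(within.max()) if within.size else None
    min_between = int(between.min()) if between.size else None
    return {
        "max_within_group_diff": max_within,
        "min_between_genotype_diff": min_between,
        "gap_holds": bool(
            within.size == 0
            or between.size == 0
            or max_within < min_between
        ),
    }
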