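"""Threshold-based duplicate (clonal cluster) calling and the cluster census.

Potato and other vegetatively propagated crops accumulate essentially no
marker differences between true duplicates; a small number of band
differences (scoring error, somatic mutation) still indicates a common clone.
Accession pairs differing at no more than a small threshold — five bands by
default — are therefore linked, and the connected components of the resulting
graph (single-linkage transitive closure) are reported as duplicate groups.
Within a chained group the largest observed pairwise difference may exceed
the threshold; the census reports the observed min–max range per group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .distances import DifferenceHistogram, DistanceResult
from .matrix import AccessionRecord


@dataclass
class DuplicateCluster:
    """One called duplicate group (>= 2 members)."""

    cluster_id: str
    members: list[str]
    min_diff: int
    max_diff: int


@dataclass
class DuplicateCensus:
    """All clusters called at one threshold, plus bookkeeping totals."""

    clusters: list[DuplicateCluster]
    n_accessions_in_clusters: int
    n_singletons: int
    n_unique_genotypes: int
    size_distribution: dict[int, int]
    threshold: int

    def member_sets(self) -> set[frozenset[str]]:
        return {frozenset(c.members) for c in self.clusters}


def call_duplicates(
    d: DistanceResult, threshold: int = 5, linkage: str = "single"
) -> DuplicateCensus:
    """Call duplicate clusters at ``diff <= threshold``.

    ``linkage="single"`` (default) takes connected components of the
    threshold graph, so chained accessions join one group even when some
    within-group pairs exceed the threshold.  ``linkage="clique"`` is a
    stricter sensitivity-analysis variant requiring every within-group pair
    to be at or below the threshold: maximal cliques are assigned greedily,
    largest first (ties by smallest member id), each accession to one group.

    Each unique genotype is either a singleton or one whole cluster, so
    ``n_unique_genotypes = n_singletons + len(clusters)``.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    n = d.n
    close = d.diff_counts <= threshold
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    iu, ju = np.nonzero(np.triu(close, 1))
    graph.add_edges_from(zip(iu.tolist(), ju.tolist()))

    if linkage == "single":
        groups = [sorted(c) for c in nx.connected_components(graph) if len(c) > 1]
    elif linkage == "clique":
        cliques = [sorted(c) for c in nx.find_cliques(graph) if len(c) > 1]
        cliques.sort(key=lambda c: (-len(c), [d.accession_ids[i] for i in c]))
        taken: set[int] = set()
        groups = []
        for c in cliques:
            remaining = [i for i in c if i not in taken]
            if len(remaining) > 1:
                groups.append(remaining)
                taken.update(remaining)
    else:
        raise ValueError(f"unknown linkage {linkage!r}")

    clusters: list[DuplicateCluster] = []
    for idx in groups:
        sub = d.diff_counts[np.ix_(idx, idx)]
        off = sub[np.triu_indices(len(idx), 1)]
        clusters.append(
            DuplicateCluster(
                cluster_id="",
                members=sorted(d.accession_ids[i] for i in idx),
                min_diff=int(off.min()),
                max_diff=int(off.max()),
            )
        )
    clusters.sort(key=lambda c: (-len(c.members), c.members[0]))
    for k, c in enumerate(clusters, start=1):
        c.cluster_id = f"C-{k}"

    n_in = sum(len(c.members) for c in clusters)
    sizes: dict[int, int] = {}
    for c in clusters:
        sizes[len(c.members)] = sizes.get(len(c.members), 0) + 1
    return DuplicateCensus(
        clusters=clusters,
        n_accessions_in_clusters=n_in,
        n_singletons=n - n_in,
        n_unique_genotypes=(n - n_in) + len(clusters),
        size_distribution=dict(sorted(sizes.items())),
        threshold=threshold,
    )


def census_table(
    census: DuplicateCensus,
    meta: Mapping[str, AccessionRecord] | None = None,
) -> pd.DataFrame:
    """One row per cluster: id, member names, size, observed difference range.

    Members are shown by passport name when metadata is supplied (falling
    back to the accession id), sorted lexicographically.  The difference
    column collapses to a single value when min equals max.
    """
    rows = []
    for c in census.clusters:
        names = sorted(
            (meta[a].name or a) if meta and a in meta else a for a in c.members
        )
        diff = (
            str(c.min_diff)
            if c.min_diff == c.max_diff
            else f"{c.min_diff} - {c.max_diff}"
        )
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "members": ", ".join(names),
                "size": len(c.members),
                "differences": diff,
            }
        )
    return pd.DataFrame(rows, columns=["cluster_id", "members", "size", "differences"])


def render_census(table: pd.DataFrame) -> str:
    """Plain-text rendering of the census table."""
    if table.empty:
        return "No duplicate clusters called.\n"
    widths = {
        col: max(len(col), *(len(str(v)) for v in table[col])) for col in table
    }
    lines = [" | ".join(col.ljust(widths[col]) for col in table)]
    lines.append("-+-".join("-" * widths[col] for col in table))
    for _, row in table.iterrows():
        lines.append(" | ".join(str(row[col]).ljust(widths[col]) for col in table))
    return "\n".join(lines) + "\n"


def write_census_csv(
    census: DuplicateCensus,
    path: str | Path,
    meta: Mapping[str, AccessionRecord] | None = None,
) -> None:
    """Long-form census CSV: one row per cluster member."""
    rows = []
    for c in census.clusters:
        for a in sorted(c.members):
            rows.append(
                {
                    "cluster_id": c.cluster_id,
                    "member": a,
                    "name": (meta[a].name if meta and a in meta else ""),
                    "size": len(c.members),
                    "min_diff": c.min_diff,
                    "max_diff": c.max_diff,
                }
            )
    pd.DataFrame(
        rows, columns=["cluster_id", "member", "name", "size", "min_diff", "max_diff"]
    ).to_csv(path, index=False)


def divergence_band(d: DistanceResult, low: int, high: int) -> int:
    """Number of unordered pairs with ``low < diff <= high``."""
    if not 0 <= low <= high:
        raise ValueError("need 0 <= low <= high")
    iu = np.triu_indices(d.n, 1)
    diffs = d.diff_counts[iu]
    return int(((diffs > low) & (diffs <= high)).sum())


def suggest_threshold(h: DifferenceHistogram) -> int | None:
    """Largest difference value below the first empty band of the histogram.

    Returns ``None`` when the histogram has no pairs or no gap.  The
    suggestion is advisory only — it is never applied automatically.
    """
    if not h.counts:
        return None
    top = max(h.counts)
    for g in range(top + 1):
        if h.counts.get(g, 0) == 0:
            return g - 1 if g > 0 else None
    return None
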