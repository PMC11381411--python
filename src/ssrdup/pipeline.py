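"""One-shot pipeline: matrix -> validation -> distances -> census -> trees.

A run either reads a band matrix (plus optional passport metadata) from disk
or simulates one, then writes every analysis artifact into an output
directory: validation summary, distance matrices (CSV and PHYLIP square),
difference histogram, duplicate census (CSV and text), bootstrap-supported
and support-collapsed Newick trees per method, and a JSON run report.
Identical configuration and seed give byte-identical artifacts; on failure,
files written by the failing run are removed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from . import distances as dist
from . import duplicates as dup
from . import simulate as sim
from . import trees as trees_mod
from .matrix import (
    AccessionRecord,
    BandMatrix,
    Dialect,
    read_band_matrix,
    read_metadata,
    validate_matrix,
    write_band_matrix,
    write_metadata,
)


class PipelineError(RuntimeError):
    """An upstream failure, labelled with the stage that raised it."""


@dataclass
class RunConfig:
    """Settings of one pipeline run; defaults follow the study protocol:
    duplicate threshold 5 differences, 500 bootstrap replicates, branches
    under 75% support collapsed."""

    matrix_path: str | None = None
    metadata_path: str | None = None
    simulate: sim.SimConfig | None = None
    dialect: Dialect = field(default_factory=Dialect)
    threshold: int = 5
    linkage: str = "single"
    tree_methods: tuple[str, ...] = ("upgma", "nj")
    n_replicates: int = 500
    support_collapse: float = 75.0
    seed: int = 0
    outdir: str = "ssrdup_out"

    def validate(self) -> None:
        if (self.matrix_path is None) == (self.simulate is None):
            raise PipelineError(
                "config: provide exactly one of matrix_path or simulate"
            )
        for m in self.tree_methods:
            if m not in ("upgma", "nj"):
                raise PipelineError(f"config: unknown tree method {m!r}")


@dataclass
class RunReport:
    """Computed summaries plus paths of the written artifacts."""

    n_accessions: int
    n_fragments: int
    n_polymorphic: int
    n_missing_cells: int
    mean_difference: float
    histogram_low_end: dict[int, int]
    n_clusters: int
    n_accessions_in_clusters: int
    n_singletons: int
    n_unique_genotypes: int
    size_distribution: dict[int, int]
    threshold: int
    census_consistent_with_histogram: bool
    tree_log: dict[str, dict]
    artifacts: dict[str, str]
    truth_recovered: bool | None = None

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        payload["histogram_low_end"] = {
            str(k): v for k, v in self.histogram_low_end.items()
        }
        payload["size_distribution"] = {
            str(k): v for k, v in self.size_distribution.items()
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _census_vs_histogram(
    census: dup.DuplicateCensus, d: dist.DistanceResult
) -> bool:
    """Within-cluster pairs at <= threshold must equal the histogram mass there.

    Under single linkage every pair at or below the threshold lies inside
    one cluster, so the two counts agree; this is the run's internal
    bookkeeping cross-check.
    """
    import numpy as np

    idx = {a: i for i, a in enumerate(d.accession_ids)}
    t = census.threshold
    within = 0
    for c in census.clusters:
        rows = [idx[a] for a in c.members]
        sub = d.diff_counts[np.ix_(rows, rows)]
        within += int((sub[np.triu_indices(len(rows), 1)] <= t).sum())
    hist = dist.difference_histogram(d)
    return within == hist.pairs_at_most(t)


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute every stage and write all artifacts under ``cfg.outdir``."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def out(name: str) -> Path:
        p = outdir / name
        written.append(p)
        return p

    try:
        return _run(cfg, out)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"{_stage_of(exc)}: {exc}") from exc


def _stage_of(exc: Exception) -> str:
    from . import distances, duplicates, matrix, simulate, trees

    mod = type(exc).__module__
    names = {
        matrix.__name__: "matrix",
        distances.__name__: "distances",
        duplicates.__name__: "duplicates",
        trees.__name__: "trees",
        simulate.__name__: "simulate",
    }
    return names.get(mod, "pipeline")


def _run(cfg: RunConfig, out) -> RunReport:
    artifacts: dict[str, str] = {}
    truth = None
    meta: Mapping[str, AccessionRecord] | None = None

    if cfg.simulate is not None:
        m, truth = sim.generate_collection(cfg.simulate)
        meta = sim.generate_metadata(truth, cfg.simulate)
        p = out("matrix.csv")
        write_band_matrix(m, p)
        artifacts["matrix"] = str(p)
        p = out("metadata.csv")
        write_metadata(meta, p)
        artifacts["metadata"] = str(p)
        p = out("truth.csv")
        sim.write_truth_csv(truth, p)
        artifacts["truth"] = str(p)
    else:
        m = read_band_matrix(cfg.matrix_path, cfg.dialect)
        if cfg.metadata_path:
            meta = read_metadata(cfg.metadata_path)

    report_v = validate_matrix(m)
    p = out("validation.json")
    p.write_text(json.dumps(dataclasses.asdict(report_v), indent=2) + "\n")
    artifacts["validation"] = str(p)

    d = dist.pairwise_differences(m)
    p = out("distances.csv")
    dist.write_square_csv(d, p)
    artifacts["distances_csv"] = str(p)
    p = out("distances.phy")
    dist.write_phylip(d, p)
    artifacts["distances_phylip"] = str(p)

    hist = dist.difference_histogram(d)
    p = out("histogram.csv")
    dist.write_histogram_csv(hist, p)
    artifacts["histogram"] = str(p)

    census = dup.call_duplicates(d, threshold=cfg.threshold, linkage=cfg.linkage)
    p = out("census.csv")
    dup.write_census_csv(census, p, meta)
    artifacts["census_csv"] = str(p)
    table = dup.census_table(census, meta)
    p = out("census.txt")
    p.write_text(dup.render_census(table))
    artifacts["census_txt"] = str(p)

    tree_log: dict[str, dict] = {}
    for method in cfg.tree_methods:
        t = trees_mod.bootstrap_support(
            m, method=method, n_replicates=cfg.n_replicates, seed=cfg.seed
        )
        p = out(f"tree_{method}.nwk")
        p.write_text(trees_mod.to_newick(t))
        artifacts[f"tree_{method}"] = str(p)
        collapsed = trees_mod.collapse_branches(t, cfg.support_collapse)
        p = out(f"tree_{method}_collapsed.nwk")
        p.write_text(trees_mod.to_newick(collapsed))
        artifacts[f"tree_{method}_collapsed"] = str(p)
        tree_log[method] = dict(t.log)

    truth_recovered = None
    if truth is not None:
        truth_recovered = census.member_sets() == sim.truth_clusters(truth)

    report = RunReport(
        n_accessions=report_v.n_accessions,
        n_fragments=report_v.n_fragments,
        n_polymorphic=report_v.n_polymorphic,
        n_missing_cells=report_v.n_missing_cells,
        mean_difference=dist.mean_difference(d),
        histogram_low_end={
            k: hist.counts.get(k, 0) for k in range(cfg.threshold + 1)
        },
        n_clusters=len(census.clusters),
        n_accessions_in_clusters=census.n_accessions_in_clusters,
        n_singletons=census.n_singletons,
        n_unique_genotypes=census.n_unique_genotypes,
        size_distribution=census.size_distribution,
        threshold=cfg.threshold,
        census_consistent_with_histogram=_census_vs_histogram(census, d),
        tree_log=tree_log,
        artifacts=artifacts,
        truth_recovered=truth_recovered,
    )
    p = out("report.json")
    p.write_text(report.to_json() + "\n")
    return report
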